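"""Synthetic point datasets with the statistical structure the analysis assumes.

The study system is a survey of agricultural topsoil: a few hundred sites
with laboratory (reference-assay) concentrations of Cr, Pb, Cd, As and Ni,
and a cheap field-sensor (portable XRF) measurement on a calibration subset.
The generator draws spatially autocorrelated, cross-correlated Gaussian
random fields, transforms them to lognormal margins matching configured
means/SDs (soil metal concentrations are right-skewed and strictly
positive), and derives sensor readings as a linear function of truth plus
Gaussian noise calibrated to a target R-squared.

Default marginal targets, sensor fidelities and sample sizes emulate a
351-site survey with a 97-sample sensor-calibrated subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .variogram import VariogramModel, model_gamma

__all__ = [
    "METALS",
    "DEFAULT_MARGINALS",
    "DEFAULT_SENSOR_R2",
    "SyntheticConfig",
    "simulate_fields",
    "sensor_surrogate",
    "split_calibration_validation",
]

METALS = ("Cr", "Pb", "Cd", "As", "Ni")

# (mean, sd) in mg/kg of the reference-assay concentrations being emulated
DEFAULT_MARGINALS = {
    "Cr": (43.79, 16.86),
    "Pb": (22.68, 14.64),
    "Cd": (0.37, 0.24),
    "As": (12.59, 6.77),
    "Ni": (20.31, 8.27),
}

# squared correlation of the cheap sensor against the reference assay
DEFAULT_SENSOR_R2 = {"Cr": 0.66, "Pb": 0.55, "Cd": 0.60, "Ni": 0.65, "As": 0.44}

SENSOR_FLOOR = 0.001  # mg/kg; sensor readings are clamped to stay positive


def _default_variograms() -> dict[str, VariogramModel]:
    # unit-variance scale of the underlying Gaussian fields; a moderate
    # nugget and a range a fraction of the domain span are typical of
    # regional soil-metal surveys
    return {m: VariogramModel("spherical", 0.3, 0.7, 12_000.0) for m in METALS}


def _default_cross_corr(k: int) -> np.ndarray:
    # metals from shared (lithogenic + anthropogenic) sources correlate
    # moderately; a constant 0.5 off-diagonal is PSD for any k
    return np.full((k, k), 0.5) + 0.5 * np.eye(k)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic survey generator."""

    n_sites: int = 351
    domain_extent: tuple[float, float] = (40_000.0, 45_000.0)  # m
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    variograms: dict[str, VariogramModel] = field(default_factory=_default_variograms)
    cross_corr: np.ndarray | None = None
    sensor_r2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SENSOR_R2))
    sensor_bias: tuple[float, float] = (1.0, 0.0)  # slope, intercept
    n_calibration: int = 97
    ph_mean: float = 5.8
    ph_sd: float = 1.1
    seed: int = 0

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(self.marginals)

    def __post_init__(self):
        k = len(self.marginals)
        if self.cross_corr is None:
            self.cross_corr = _default_cross_corr(k)
        self.cross_corr = np.asarray(self.cross_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        if not (0 < self.n_calibration < self.n_sites):
            raise ValueError("n_calibration must be in (0, n_sites)")
        if any(e <= 0 for e in self.domain_extent):
            raise ValueError("domain_extent must be positive")
        for m, (mean, sd) in self.marginals.items():
            if mean <= 0 or sd <= 0:
                raise ValueError(f"marginal mean and sd for {m!r} must be > 0")
        for m, r2 in self.sensor_r2.items():
            if not (0 < r2 <= 1):
                raise ValueError(f"sensor target R^2 for {m!r} must be in (0, 1]")
        k = len(self.marginals)
        C = self.cross_corr
        if C.shape != (k, k):
            raise ValueError(f"cross-correlation matrix must be {k}x{k}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("cross-correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("cross-correlation matrix must have unit diagonal")
        lo = float(np.linalg.eigvalsh(C).min())
        if lo < -1e-10:
            raise ValueError(
                f"cross-correlation matrix not positive semidefinite "
                f"(min eigenvalue {lo:g})"
            )
        for m in self.marginals:
            if m not in self.variograms:
                raise ValueError(f"missing variogram spec for {m!r}")
            if m not in self.sensor_r2:
                raise ValueError(f"missing sensor R^2 for {m!r}")


def _spatial_factor(coords: np.ndarray, model: VariogramModel) -> np.ndarray | None:
    """Cholesky factor of the site correlation matrix implied by a variogram.

    Returns None for a zero-sill (constant-field) model. The correlation is
    C(h)/sill with C(h) = sill - gamma(h) for h > 0 and C(0) = sill.
    """
    sill = model.sill
    if sill <= 0:
        return None
    D = squareform(pdist(coords))
    C = np.where(D == 0.0, sill, sill - model_gamma(model, D))
    R = C / sill
    return np.linalg.cholesky(R + 1e-10 * np.eye(len(coords)))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_fields(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a survey sample table, deterministic given ``config.seed``.

    Site coordinates are uniform over the rectangular domain. Each metal is a
    Gaussian random field with the configured variogram (correlation built
    from sill - gamma(h), factorized by Cholesky), cross-correlated across
    metals by mixing shared innovations with the Cholesky factor of the
    cross-correlation matrix (an intrinsic-correlation construction, exact
    when all metals share one variogram shape), then mapped to lognormal
    margins with the configured mean/sd. A zero-sill variogram yields a field
    constant at its target mean. Sensor columns are simulated at every site;
    calibration/validation masking is a separate step.

    Columns: id, x, y, pH, {metal}_lab, {metal}_pxrf.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    metals = config.metals
    k = len(metals)

    coords = rng.uniform((0.0, 0.0), config.domain_extent, size=(n, 2))

    L = np.linalg.cholesky(config.cross_corr + 1e-12 * np.eye(k))
    E = rng.standard_normal((n, k))
    F = E @ L.T  # cross-correlated standard innovations, one column per metal

    table = {"id": np.arange(n), "x": coords[:, 0], "y": coords[:, 1]}

    # pH: spatially smooth field sharing the first metal's spatial structure
    ph_factor = _spatial_factor(coords, config.variograms[metals[0]])
    ph_field = ph_factor @ rng.standard_normal(n) if ph_factor is not None else np.zeros(n)
    table["pH"] = np.clip(config.ph_mean + config.ph_sd * ph_field, 3.0, 9.0)

    lab = {}
    for j, m in enumerate(metals):
        mean, sd = config.marginals[m]
        vgm = config.variograms[m]
        A = _spatial_factor(coords, vgm)
        if A is None:
            lab[m] = np.full(n, mean)
        else:
            z = A @ F[:, j]
            mu, sigma = _lognormal_params(mean, sd)
            lab[m] = np.exp(mu + sigma * z)
        table[f"{m}_lab"] = lab[m]

    slope, intercept = config.sensor_bias
    for m in metals:
        table[f"{m}_pxrf"] = sensor_surrogate(
            lab[m], config.sensor_r2[m], (slope, intercept), rng=rng
        )
    return pd.DataFrame(table)


def sensor_surrogate(
    true_values: np.ndarray,
    target_r2: float,
    bias: tuple[float, float] = (1.0, 0.0),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy linear sensor reading with an analytically set signal-to-noise.

    Returns slope*true + intercept + eps with eps i.i.d. Gaussian whose
    variance slope^2 * var(true) * (1 - R2) / R2 makes the expected squared
    correlation with truth equal ``target_r2``. ``target_r2 = 1`` is exactly
    noise-free. Outputs are clamped at a small positive floor.
    """
    if not (0 < target_r2 <= 1):
        raise ValueError("target_r2 must be in (0, 1]")
    true_values = np.asarray(true_values, dtype=float)
    if true_values.size < 3:
        raise ValueError("need at least 3 true values")
    if rng is None:
        rng = np.random.default_rng(seed)
    slope, intercept = bias
    out = slope * true_values + intercept
    if target_r2 < 1:
        noise_sd = abs(slope) * true_values.std() * np.sqrt((1 - target_r2) / target_r2)
        out = out + rng.normal(0.0, noise_sd, size=true_values.shape)
    return np.maximum(out, SENSOR_FLOOR)


def split_calibration_validation(
    samples: pd.DataFrame, n_calibration: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint calibration/validation partition.

    Sensor (``*_pxrf``) columns are retained only in the calibration part;
    in the validation part they are set missing — the study design measures
    the cheap sensor on the calibration subset only.
    """
    n = len(samples)
    if not (0 < n_calibration < n):
        raise ValueError("n_calibration must be in (0, n_samples)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_calibration])
    val_idx = np.sort(perm[n_calibration:])
    cal = samples.iloc[cal_idx].reset_index(drop=True)
    val = samples.iloc[val_idx].reset_index(drop=True).copy()
    sensor_cols = [c for c in samples.columns if c.endswith("_pxrf")]
    val[sensor_cols] = np.nan
    return cal, val
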