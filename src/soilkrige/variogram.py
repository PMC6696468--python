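"""Empirical (cross-)semivariogram estimation and permissible model fitting.

The semivariogram gamma(h) summarizes spatial dependence as half the mean
squared difference between values separated by lag h; the cross-variogram
generalizes it to half the mean product of the increments of two variables
observed at the same pair of sites. Models are fitted by weighted least
squares with Cressie weights N(h)/gamma_model(h)^2. A linear model of
coregionalization (LMC) expresses all direct and cross variograms of a set
of variables as combinations of shared basic structures with positive
semidefinite coefficient matrices, which guarantees a valid co-kriging
system.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

__all__ = [
    "FAMILIES",
    "EmpiricalVariogram",
    "VariogramModel",
    "CoregionalizationModel",
    "EmptyVariogramError",
    "empirical_semivariogram",
    "empirical_cross_variogram",
    "model_gamma",
    "fit_model",
    "fit_lmc",
    "wls_objective",
]

FAMILIES = ("spherical", "exponential", "gaussian")


class EmptyVariogramError(ValueError):
    """No sample pairs fall inside the requested lag structure."""


def _unit_gamma(family: str, u: np.ndarray) -> np.ndarray:
    """Unit-sill, unit-range variogram shape g(u), u = h/range >= 0.

    Exponential and Gaussian use the practical-range convention: g reaches
    ~0.95 of the sill at u = 1. The spherical model attains its sill exactly
    at u = 1.
    """
    u = np.asarray(u, dtype=float)
    if family == "spherical":
        uc = np.minimum(u, 1.0)
        return 1.5 * uc - 0.5 * uc**3
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * u)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * u**2)
    if family == "nugget":
        return np.ones_like(u)
    raise ValueError(f"unknown variogram family {family!r}")


@dataclass(frozen=True)
class VariogramModel:
    """Permissible isotropic variogram model nugget + psill * g(h/range)."""

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        return model_gamma(self, h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range_,
        }


def model_gamma(model: VariogramModel, h) -> np.ndarray:
    """Evaluate gamma(h) with the convention gamma(0) = 0.

    For h > 0, gamma = nugget + partial_sill * g(h/range); the nugget is a
    discontinuity at the origin.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distance h must be >= 0")
    g = model.nugget + model.partial_sill * _unit_gamma(model.family, h / model.range_)
    out = np.where(h == 0.0, 0.0, g)
    return out if out.ndim else float(out)


@dataclass
class EmpiricalVariogram:
    """Binned empirical (cross-)semivariogram.

    ``variable_a == variable_b`` marks a direct variogram; cross-variogram
    values may be negative, direct values are non-negative.
    """

    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    variable_a: str
    variable_b: str

    def __post_init__(self):
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        n = len(self.lag_centers)
        if not (len(self.semivariance) == len(self.pair_counts) == n):
            raise ValueError("lag_centers, semivariance, pair_counts must align")
        if n and (np.any(np.diff(self.lag_centers) <= 0) or np.any(self.lag_centers <= 0)):
            raise ValueError("lag_centers must be strictly increasing and positive")

    @property
    def is_direct(self) -> bool:
        return self.variable_a == self.variable_b

    @property
    def max_lag(self) -> float:
        return float(self.lag_centers[-1]) if len(self.lag_centers) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lag_centers,
                "gamma": self.semivariance,
                "count": self.pair_counts,
            }
        )


def _pair_arrays(samples: pd.DataFrame, columns: list[str]):
    """Coordinates and values of the rows where every requested column is present."""
    cols = ["x", "y"] + columns
    sub = samples.dropna(subset=cols)
    coords = sub[["x", "y"]].to_numpy(dtype=float)
    values = [sub[c].to_numpy(dtype=float) for c in columns]
    return coords, values


def _bin_pairs(dist, cross_products, lag_width, n_lags, max_dist):
    if max_dist is None:
        max_dist = 0.5 * float(dist.max()) if dist.size else 0.0
    if lag_width is None:
        if n_lags is None:
            n_lags = 12
        lag_width = max_dist / n_lags
    if lag_width <= 0:
        raise ValueError("lag_width must be > 0")
    if n_lags is None:
        n_lags = int(np.ceil(max_dist / lag_width))
    # zero-separation pairs carry no lag information; duplicates are the
    # kriging module's concern
    keep = (dist <= max_dist) & (dist > 0)
    dist = dist[keep]
    cross_products = cross_products[keep]
    if dist.size == 0:
        raise EmptyVariogramError("no sample pairs within max_dist")
    idx = np.minimum((dist / lag_width).astype(int), n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=cross_products, minlength=n_lags)
    dsums = np.bincount(idx, weights=dist, minlength=n_lags)
    nonempty = counts > 0
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    centers = dsums[nonempty] / counts[nonempty]
    return centers, gamma, counts[nonempty]


def empirical_semivariogram(
    samples: pd.DataFrame,
    variable: str,
    lag_width: float | None = None,
    n_lags: int | None = 12,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator: bin b holds (1/2N_b) * sum (Z(x_i) - Z(x_j))^2."""
    coords, (z,) = _pair_arrays(samples, [variable])
    if len(z) < 2:
        raise ValueError("need at least 2 samples with the variable present")
    d = pdist(coords)
    dz = pdist(z[:, None], metric=lambda u, v: (u[0] - v[0]) ** 2)
    centers, gamma, counts = _bin_pairs(d, dz, lag_width, n_lags, max_dist)
    return EmpiricalVariogram(centers, gamma, counts, variable, variable)


def empirical_cross_variogram(
    samples: pd.DataFrame,
    variable_a: str,
    variable_b: str,
    lag_width: float | None = None,
    n_lags: int | None = 12,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Co-located cross-variogram: (1/2N_b) * sum dZa(i,j) * dZb(i,j)."""
    coords, (za, zb) = _pair_arrays(samples, [variable_a, variable_b])
    if len(za) < 2:
        raise EmptyVariogramError("need at least 2 co-located samples of both variables")
    d = pdist(coords)
    i, j = np.triu_indices(len(za), k=1)
    prod = (za[i] - za[j]) * (zb[i] - zb[j])
    centers, gamma, counts = _bin_pairs(d, prod, lag_width, n_lags, max_dist)
    return EmpiricalVariogram(centers, gamma, counts, variable_a, variable_b)


_WEIGHT_FLOOR = 1e-12


def wls_objective(emp: EmpiricalVariogram, model: VariogramModel) -> float:
    """Cressie-weighted SSE: sum_b N_b / gamma_model(h_b)^2 * (gamma_b - gamma_model(h_b))^2."""
    gm = model_gamma(model, emp.lag_centers)
    w = emp.pair_counts / np.maximum(gm, _WEIGHT_FLOOR) ** 2
    return float(np.sum(w * (emp.semivariance - gm) ** 2))


def _fit_single_family(emp: EmpiricalVariogram, family: str) -> tuple[VariogramModel, float]:
    h = emp.lag_centers
    g = emp.semivariance
    max_lag = emp.max_lag
    gmax = float(g.max())

    def objective(p):
        nugget, psill, rng = p
        m = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-12))
        return wls_objective(emp, m)

    bounds = [(0.0, 3.0 * gmax), (0.0, 3.0 * gmax), (1e-6 * max_lag, 2.0 * max_lag)]
    n0 = max(float(g[0]) * 0.5, 0.0)
    starts = [
        (n0, max(gmax - n0, 1e-3 * gmax), 0.5 * max_lag),
        (0.0, gmax, 0.3 * max_lag),
        (0.5 * gmax, 0.5 * gmax, max_lag),
        (0.0, gmax, 0.1 * max_lag),
    ]
    best = None
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):  # pragma: no cover
        raise RuntimeError(f"variogram fit failed for family {family!r}")
    nugget, psill, rng = best.x
    model = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0), max(rng, 1e-12))
    return model, float(best.fun)


def fit_model(emp: EmpiricalVariogram, family: str = "auto") -> VariogramModel:
    """Fit nugget/partial sill/range by Cressie-weighted least squares.

    With ``family="auto"`` all three standard families are tried and the one
    with the lowest weighted SSE wins. An all-zero empirical variogram (a
    constant field) degenerates to nugget = partial sill = 0.
    """
    if len(emp.lag_centers) < 3:
        raise ValueError("need at least 3 non-empty lags to fit a variogram model")
    if np.allclose(emp.semivariance, 0.0):
        fam = "spherical" if family == "auto" else family
        return VariogramModel(fam, 0.0, 0.0, emp.max_lag)
    candidates = FAMILIES if family == "auto" else (family,)
    fits = [_fit_single_family(emp, fam) for fam in candidates]
    model, _ = min(fits, key=lambda t: t[1])
    return model


@dataclass
class CoregionalizationModel:
    """Linear model of coregionalization over a set of variables.

    Every direct and cross variogram is gamma_ij(h) = sum_s B_s[i,j] * g_s(h)
    with shared basic structures g_s (one of them typically a nugget) and
    positive semidefinite coefficient matrices B_s.
    """

    variables: tuple[str, ...]
    structures: list[tuple[str, float]]  # (family, range); family may be "nugget"
    matrices: list[np.ndarray] = field(default_factory=list)

    PSD_TOL = -1e-8

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        k = len(self.variables)
        for (fam, rng), B in zip(self.structures, self.matrices):
            if B.shape != (k, k):
                raise ValueError("coregionalization matrix shape mismatch")
            if not np.allclose(B, B.T, atol=1e-10):
                raise ValueError("coregionalization matrices must be symmetric")
            if fam != "nugget" and rng <= 0:
                raise ValueError("structure range must be > 0")
            lo = float(np.linalg.eigvalsh(B).min())
            if lo < self.PSD_TOL:
                raise ValueError(f"coregionalization matrix not PSD (min eigenvalue {lo:g})")

    def _index(self, variable: str) -> int:
        return self.variables.index(variable)

    def gamma(self, variable_a: str, variable_b: str, h) -> np.ndarray:
        """gamma_ab(h) with gamma_ab(0) = 0 for direct and cross terms alike."""
        h = np.asarray(h, dtype=float)
        a, b = self._index(variable_a), self._index(variable_b)
        g = np.zeros_like(h, dtype=float)
        for (fam, rng), B in zip(self.structures, self.matrices):
            u = h if fam == "nugget" else h / rng
            g = g + B[a, b] * _unit_gamma(fam, u)
        out = np.where(h == 0.0, 0.0, g)
        return out if out.ndim else float(out)

    def direct_sill(self, variable: str) -> float:
        a = self._index(variable)
        return float(sum(B[a, a] for B in self.matrices))

    def cross_sill(self, variable_a: str, variable_b: str) -> float:
        a, b = self._index(variable_a), self._index(variable_b)
        return float(sum(B[a, b] for B in self.matrices))


def _nearest_psd(B: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    return (v * np.maximum(w, 0.0)) @ v.T


def fit_lmc(
    variograms: dict[tuple[str, str], EmpiricalVariogram],
    structures: list[tuple[str, float]],
) -> CoregionalizationModel:
    """Fit an LMC by per-variogram WLS on shared structures, then PSD projection.

    ``variograms`` maps unordered variable pairs to empirical (cross-)
    variograms; every variable's direct variogram and the cross-variogram of
    each modeled pair must be present. Weights are N_b / max(gamma_b, eps)^2.
    Each coefficient matrix is projected to the nearest positive semidefinite
    matrix by eigenvalue clipping.
    """
    pairs = {tuple(k): v for k, v in variograms.items()}
    variables = tuple(sorted({v for k in pairs for v in k}))
    k = len(variables)
    for v in variables:
        if (v, v) not in pairs:
            raise ValueError(f"missing direct variogram for {v!r}")
    for a, b in itertools.combinations(variables, 2):
        if (a, b) not in pairs and (b, a) not in pairs:
            raise ValueError(f"missing cross-variogram for pair ({a!r}, {b!r})")

    n_s = len(structures)
    coeffs = {}
    for key, emp in pairs.items():
        h = emp.lag_centers
        design = np.column_stack(
            [_unit_gamma(fam, h if fam == "nugget" else h / rng) for fam, rng in structures]
        )
        w = np.sqrt(emp.pair_counts / np.maximum(np.abs(emp.semivariance), _WEIGHT_FLOOR) ** 2)
        sol, *_ = np.linalg.lstsq(design * w[:, None], emp.semivariance * w, rcond=None)
        coeffs[frozenset(key) if key[0] != key[1] else key[0]] = sol

    matrices = []
    for s in range(n_s):
        B = np.zeros((k, k))
        for i, a in enumerate(variables):
            B[i, i] = coeffs[a][s]
            for j in range(i + 1, k):
                b = variables[j]
                B[i, j] = B[j, i] = coeffs[frozenset((a, b))][s]
        matrices.append(_nearest_psd(B))
    return CoregionalizationModel(variables, list(structures), matrices)
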