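"""Indicator kriging and the toxicity-weighted multi-variable risk surface.

Observations are coded 1 where the value reaches a threshold (exceedance)
and 0 below it; ordinary kriging of those indicators estimates, cell by
cell, the probability that the threshold is exceeded. Multi-variable
indicator kriging (MVIK) combines the per-metal exceedance-probability
surfaces as a convex combination weighted by normalized toxicity response
coefficients (Cd 30, As 10, Pb 5, Cr 2, Ni 5 by default), yielding one
composite pollution-risk map.

Orientation note: the indicators code exceedance (Z >= z) and the kriged
surface is read as a pollution-risk probability — high composite values
mean high multi-metal pollution risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kriging import GridSpec, ok_predict
from .variogram import VariogramModel, empirical_semivariogram, fit_model

__all__ = [
    "TOXICITY_COEFFICIENTS",
    "IndicatorField",
    "CompositeRiskField",
    "indicator_transform",
    "ik_probability",
    "toxicity_weights",
    "mvik_combine",
]

# toxicity response coefficients r_i used to weight per-metal risk surfaces
TOXICITY_COEFFICIENTS = {"Cd": 30.0, "As": 10.0, "Pb": 5.0, "Cr": 2.0, "Ni": 5.0}


@dataclass
class IndicatorField:
    """Kriged exceedance-probability surface for one variable and threshold."""

    variable: str
    threshold: float
    spec: GridSpec
    probability: np.ndarray  # (n_rows, n_cols), clamped to [0, 1]
    model: VariogramModel | None = None

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float).reshape(
            (self.spec.n_rows, self.spec.n_cols)
        )
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class CompositeRiskField:
    """Toxicity-weighted convex combination of indicator-kriging surfaces."""

    spec: GridSpec
    probability: np.ndarray
    weights: dict[str, float]
    coefficients: dict[str, float]

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float).reshape(
            (self.spec.n_rows, self.spec.n_cols)
        )
        w = np.array(list(self.weights.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-10 or np.any(w < 0):
            raise ValueError("weights must be non-negative and sum to 1")


def indicator_transform(values, threshold: float) -> np.ndarray:
    """Exceedance indicator: 1 where value >= threshold, else 0."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = np.asarray(values, dtype=float)
    return (values >= threshold).astype(float)


def ik_probability(
    samples: pd.DataFrame,
    variable: str,
    threshold: float,
    spec: GridSpec,
    n_lags: int = 12,
) -> IndicatorField:
    """Krige threshold-exceedance indicators over a grid, clamped to [0, 1].

    The indicator data get their own variogram fit (auto family); if the fit
    degenerates or fails, a pure-nugget model at the indicator variance is
    used with a warning. When only one indicator class is present the field
    is the constant 0 or 1.
    """
    sub = samples.dropna(subset=["x", "y", variable]).copy()
    ind = indicator_transform(sub[variable].to_numpy(dtype=float), threshold)
    if ind.min() == ind.max():
        warnings.warn(
            f"all indicators equal {ind[0]:.0f} for {variable!r}; returning constant field"
        )
        const = np.full((spec.n_rows, spec.n_cols), float(ind[0]))
        return IndicatorField(variable, threshold, spec, const, None)
    sub["_indicator"] = ind
    try:
        emp = empirical_semivariogram(sub, "_indicator", n_lags=n_lags)
        model = fit_model(emp, family="auto")
        if model.sill <= 0:
            raise RuntimeError("degenerate indicator variogram")
    except Exception:
        warnings.warn(f"indicator variogram fit failed for {variable!r}; using pure nugget")
        model = VariogramModel("spherical", float(ind.var()), 0.0, 1.0)
    est, _, _ = ok_predict(sub, "_indicator", model, spec.cell_centers())
    prob = np.clip(est, 0.0, 1.0)
    return IndicatorField(variable, threshold, spec, prob, model)


def toxicity_weights(coefficients: dict[str, float]) -> dict[str, float]:
    """Normalize toxicity response coefficients: w_i = r_i / sum_j r_j."""
    vals = np.array(list(coefficients.values()), dtype=float)
    if vals.size == 0 or np.any(vals <= 0):
        raise ValueError("all toxicity coefficients must be > 0")
    w = vals / vals.sum()
    return dict(zip(coefficients.keys(), w))


def mvik_combine(
    fields: list[IndicatorField], weights: dict[str, float]
) -> CompositeRiskField:
    """Cell-wise weighted combination of per-metal exceedance probabilities."""
    if not fields:
        raise ValueError("need at least one indicator field")
    spec = fields[0].spec
    for f in fields[1:]:
        if f.spec != spec:
            raise ValueError("all indicator fields must share an identical grid")
    missing = [f.variable for f in fields if f.variable not in weights]
    if missing:
        raise ValueError(f"missing weights for {missing}")
    w = np.array([weights[f.variable] for f in fields], dtype=float)
    if abs(w.sum() - 1.0) > 1e-10:
        raise ValueError("weights must sum to 1")
    composite = sum(wi * f.probability for wi, f in zip(w, fields))
    used = {f.variable: weights[f.variable] for f in fields}
    return CompositeRiskField(spec, composite, used, dict(TOXICITY_COEFFICIENTS))
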