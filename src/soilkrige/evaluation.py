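"""Validation metrics and interpolation-method comparison tables.

R-squared is the squared Pearson correlation between observed and predicted
values (the scatter-against-identity reading); RMSE and signed mean bias
measure accuracy; Lin's concordance correlation coefficient penalizes both
dispersion and location shift, so it is bounded by |r|. The comparison
table reports each metric per metal for ordinary kriging and co-kriging
plus the percent change between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "r_squared",
    "rmse",
    "lin_concordance",
    "bias",
    "relative_change",
    "comparison_table",
]


def _pair(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    return o, p


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted."""
    o, p = _pair(observed, predicted)
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    if o.std() == 0 or p.std() == 0:
        raise ValueError("R^2 undefined for zero-variance input")
    r = np.corrcoef(o, p)[0, 1]
    return float(r**2)


def r_squared_sse(observed, predicted) -> float:
    """1 - SSE/SST form (can be negative); computed for diagnostics."""
    o, p = _pair(observed, predicted)
    sst = np.sum((o - o.mean()) ** 2)
    if sst == 0:
        raise ValueError("R^2 undefined for zero-variance observations")
    return float(1.0 - np.sum((p - o) ** 2) / sst)


def rmse(observed, predicted) -> float:
    """Root mean squared prediction error."""
    o, p = _pair(observed, predicted)
    if o.size < 1:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def lin_concordance(observed, predicted) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2); identical
    constant vectors are defined as perfectly concordant (1).
    """
    o, p = _pair(observed, predicted)
    if o.size < 3:
        raise ValueError("need at least 3 pairs")
    vo, vp = o.var(), p.var()
    dm = o.mean() - p.mean()
    den = vo + vp + dm**2
    if den == 0:
        return 1.0
    cov = ((o - o.mean()) * (p - p.mean())).mean()
    return float(2.0 * cov / den)


def bias(observed, predicted) -> float:
    """Signed mean error mean(predicted - observed)."""
    o, p = _pair(observed, predicted)
    if o.size < 1:
        raise ValueError("need at least 1 pair")
    return float(np.mean(p - o))


def relative_change(metric_ok: float, metric_cok: float) -> float:
    """Percent change from OK to COK, rounded to 2 decimals for reports."""
    if metric_ok == 0:
        raise ValueError("zero baseline metric")
    return round(100.0 * (metric_cok - metric_ok) / metric_ok, 2)


def comparison_table(
    observed: dict[str, np.ndarray],
    predicted_ok: dict[str, np.ndarray],
    predicted_cok: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-metal OK vs COK metric table with percent-difference rows.

    All three dicts are keyed by metal; rows mirror the familiar layout
    element / method / R^2 / concordance / RMSE / bias.
    """
    rows = []
    for m, obs in observed.items():
        mo = {
            "r2": r_squared(obs, predicted_ok[m]),
            "concordance": lin_concordance(obs, predicted_ok[m]),
            "rmse": rmse(obs, predicted_ok[m]),
            "bias": bias(obs, predicted_ok[m]),
        }
        mc = {
            "r2": r_squared(obs, predicted_cok[m]),
            "concordance": lin_concordance(obs, predicted_cok[m]),
            "rmse": rmse(obs, predicted_cok[m]),
            "bias": bias(obs, predicted_cok[m]),
        }
        rows.append({"element": m, "method": "OK", **mo})
        rows.append({"element": m, "method": "COK", **mc})
        rows.append(
            {
                "element": m,
                "method": "difference_pct",
                **{
                    k: relative_change(mo[k], mc[k]) if mo[k] != 0 else np.nan
                    for k in ("r2", "concordance", "rmse", "bias")
                },
            }
        )
    return pd.DataFrame(rows)
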