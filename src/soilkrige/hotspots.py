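"""Getis-Ord Gi* hotspot statistic and hot/cold-spot classification.

Gi* measures, for each location, how the sum of values inside a distance
band around it (the location itself included — the "star" convention)
compares with what would be expected if values were placed at random. The
result is a z-score: large positive values flag clusters of high values
(hot spots), large negative values clusters of low values (cold spots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "HOTSPOT_CLASSES",
    "spatial_weights",
    "getis_ord_gstar",
    "classify_hotspots",
    "hotspot_analysis",
]

HOTSPOT_CLASSES = ("cold99", "cold95", "cold90", "not-significant", "hot90", "hot95", "hot99")
_CRIT = (1.645, 1.960, 2.576)  # two-sided 90 / 95 / 99% normal critical values


def spatial_weights(points: np.ndarray, band: float) -> np.ndarray:
    """Binary distance-band weights w_ij = 1 iff d(i,j) <= band, self included."""
    if band <= 0:
        raise ValueError("band must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (cdist(pts, pts) <= band).astype(float)


def getis_ord_gstar(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gi* z-score per location.

    z_i = (sum_j w_ij x_j - xbar * W_i) / (S * sqrt((n*sum_j w_ij^2 - W_i^2)/(n-1)))

    with xbar and S the global mean and population standard deviation and
    W_i = sum_j w_ij. Locations with a zero denominator (constant field, or
    a neighborhood spanning every point) get z = 0.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 locations")
    if w.shape != (n, n):
        raise ValueError("weights shape must be (n, n)")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    wsum = w.sum(axis=1)
    w2sum = (w**2).sum(axis=1)
    num = w @ x - xbar * wsum
    den = s * np.sqrt(np.maximum(n * w2sum - wsum**2, 0.0) / (n - 1))
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def classify_hotspots(z: np.ndarray) -> np.ndarray:
    """Label z-scores by two-sided 90/95/99% normal critical values."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    idx = np.digitize(z, (-_CRIT[2], -_CRIT[1], -_CRIT[0], _CRIT[0], _CRIT[1], _CRIT[2]))
    return np.asarray(HOTSPOT_CLASSES)[idx]


@dataclass
class HotspotField:
    """Per-location Gi* z-scores and classes for one analyzed variable."""

    table: pd.DataFrame  # id, x, y, value, gstar_z, class
    band: float
    variable: str


def hotspot_analysis(
    samples: pd.DataFrame, column: str, band: float
) -> HotspotField:
    """Run Gi* on point samples for one column with a distance-band weight."""
    sub = samples.dropna(subset=["x", "y", column])
    pts = sub[["x", "y"]].to_numpy(dtype=float)
    vals = sub[column].to_numpy(dtype=float)
    w = spatial_weights(pts, band)
    z = getis_ord_gstar(vals, w)
    out = pd.DataFrame(
        {
            "id": sub["id"].to_numpy() if "id" in sub else np.arange(len(sub)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "value": vals,
            "gstar_z": z,
            "class": classify_hotspots(z),
        }
    )
    return HotspotField(out, band, column)
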