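"""Ordinary kriging and ordinary co-kriging in semivariance form.

Both predictors are best linear unbiased estimators. Ordinary kriging (OK)
constrains its weights to sum to one; ordinary co-kriging (COK) adds a
secondary (covariate) variable whose weights sum to zero — the traditional
constraint set, which keeps the estimate unbiased without knowing either
mean. Systems are assembled from the (cross-)variogram in semivariance
form, so models without a finite sill would remain usable, and solved by a
single LU factorization shared across all prediction targets (the left-hand
matrix depends only on the data configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve, LinAlgError, LinAlgWarning
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, squareform, pdist

from .variogram import CoregionalizationModel, VariogramModel, model_gamma

__all__ = ["GridSpec", "PredictionGrid", "ok_predict", "cok_predict", "krige_grid"]

_JITTER = 1e-10
_VAR_FLOOR = -1e-9  # kriging variances above this are numerical noise; clamp to 0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left corner, square cells, rows x cols."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0 or self.cell_size <= 0:
            raise ValueError("grid must have positive dimensions and cell size")

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) cell-center coordinates, row-major, row 0 north."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        xs = self.x0 + (j + 0.5) * self.cell_size
        ys = self.y0 + (self.n_rows - i - 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, n_rows=100, n_cols=100, pad=0.05):
        """Grid covering a bounding box padded by a fraction on each side."""
        w, h = xmax - xmin, ymax - ymin
        x0, y0 = xmin - pad * w, ymin - pad * h
        cell = max(w * (1 + 2 * pad) / n_cols, h * (1 + 2 * pad) / n_rows)
        return cls(x0, y0, cell, n_rows, n_cols)


@dataclass
class PredictionGrid:
    """Kriged surface: estimate and kriging variance on a regular grid."""

    spec: GridSpec
    estimate: np.ndarray
    kriging_variance: np.ndarray
    variable: str
    method: str  # "OK" | "COK"

    def __post_init__(self):
        shape = (self.spec.n_rows, self.spec.n_cols)
        self.estimate = np.asarray(self.estimate, dtype=float).reshape(shape)
        self.kriging_variance = np.asarray(self.kriging_variance, dtype=float).reshape(shape)
        if np.any(self.kriging_variance < _VAR_FLOOR):
            raise ValueError("kriging variance below numerical floor")
        self.kriging_variance = np.maximum(self.kriging_variance, 0.0)


def _dedupe(coords: np.ndarray, values: np.ndarray):
    """Average conflicting values at duplicated sample locations."""
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    avg = np.bincount(inv, weights=values) / np.bincount(inv)
    warnings.warn("duplicate sample locations: conflicting values averaged")
    return uniq, avg


def _solve_augmented(A: np.ndarray, B: np.ndarray, n_data: int) -> np.ndarray:
    """Solve A X = B, adding diagonal jitter to the data block if singular."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", LinAlgWarning)
        try:
            return lu_solve(lu_factor(A), B)
        except (LinAlgError, LinAlgWarning):
            A = A.copy()
            A[np.arange(n_data), np.arange(n_data)] += _JITTER
            return lu_solve(lu_factor(A), B)


def ok_predict(
    samples: pd.DataFrame,
    variable: str,
    model: VariogramModel,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary kriging at arbitrary target points.

    Returns (estimates, kriging variances, weights) with weights of shape
    (n_targets, n_samples). Weights sum to 1; under a nugget-free model the
    predictor is exact at sample locations with zero variance.
    """
    sub = samples.dropna(subset=["x", "y", variable])
    coords = sub[["x", "y"]].to_numpy(dtype=float)
    z = sub[variable].to_numpy(dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 samples")
    coords, z = _dedupe(coords, z)
    n = len(z)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))

    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model_gamma(model, squareform(pdist(coords)))
    A[n, :n] = A[:n, n] = 1.0

    B = np.ones((n + 1, targets.shape[0]))
    B[:n, :] = model_gamma(model, cdist(coords, targets))

    sol = _solve_augmented(A, B, n)
    lam = sol[:n, :]
    est = lam.T @ z
    var = np.einsum("ij,ij->j", sol, B)
    var = np.where(var < 0, np.where(var >= _VAR_FLOOR, 0.0, var), var)
    return est, var, lam.T


def cok_predict(
    samples: pd.DataFrame,
    target_variable: str,
    covariate: str,
    lmc: CoregionalizationModel,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary co-kriging with one covariate, heterotopic data allowed.

    Rows contribute wherever the respective variable is observed: the
    target variable at its observation sites, the covariate at its own
    (possibly different) sites. Target weights sum to 1, covariate weights
    to 0. Returns (estimates, variances, weights) with weights over the
    concatenated [target sites, covariate sites] data vector.
    """
    sub_t = samples.dropna(subset=["x", "y", target_variable])
    sub_c = samples.dropna(subset=["x", "y", covariate])
    ct = sub_t[["x", "y"]].to_numpy(dtype=float)
    cc = sub_c[["x", "y"]].to_numpy(dtype=float)
    zt = sub_t[target_variable].to_numpy(dtype=float)
    zc = sub_c[covariate].to_numpy(dtype=float)
    if len(zt) < 2 or len(zc) < 2:
        raise ValueError("need at least 2 observations of target and covariate")
    ct, zt = _dedupe(ct, zt)
    cc, zc = _dedupe(cc, zc)
    nt, nc = len(zt), len(zc)
    n = nt + nc
    targets = np.atleast_2d(np.asarray(targets, dtype=float))

    A = np.zeros((n + 2, n + 2))
    A[:nt, :nt] = lmc.gamma(target_variable, target_variable, squareform(pdist(ct)))
    A[nt:n, nt:n] = lmc.gamma(covariate, covariate, squareform(pdist(cc)))
    cross = lmc.gamma(target_variable, covariate, cdist(ct, cc))
    A[:nt, nt:n] = cross
    A[nt:n, :nt] = cross.T
    A[n, :nt] = A[:nt, n] = 1.0  # sum of target weights = 1
    A[n + 1, nt:n] = A[nt:n, n + 1] = 1.0  # sum of covariate weights = 0

    B = np.zeros((n + 2, targets.shape[0]))
    B[:nt, :] = lmc.gamma(target_variable, target_variable, cdist(ct, targets))
    B[nt:n, :] = lmc.gamma(covariate, target_variable, cdist(cc, targets))
    B[n, :] = 1.0

    sol = _solve_augmented(A, B, n)
    lam = sol[:n, :]
    est = lam.T @ np.concatenate([zt, zc])
    var = np.einsum("ij,ij->j", sol, B)
    var = np.where(var < 0, np.where(var >= _VAR_FLOOR, 0.0, var), var)
    return est, var, lam.T


def krige_grid(
    samples: pd.DataFrame,
    variable: str,
    spec: GridSpec,
    method: str = "OK",
    model: VariogramModel | None = None,
    lmc: CoregionalizationModel | None = None,
    covariate: str | None = None,
    neighborhood: int | str | None = None,
) -> PredictionGrid:
    """Krige a regular grid cell-center by cell-center.

    ``neighborhood`` limits each cell's prediction to its k nearest samples
    (of the target variable); default uses all samples when n <= 200, else
    the 16 nearest. Cells are row-major with row 0 at the north edge.
    """
    sub = samples.dropna(subset=["x", "y", variable])
    if len(sub) == 0:
        raise ValueError("empty sample set")
    n = len(sub)
    if neighborhood is None:
        neighborhood = "all" if n <= 200 else 16
    centers = spec.cell_centers()

    def predict(tbl, pts):
        if method.upper() == "OK":
            if model is None:
                raise ValueError("OK requires a variogram model")
            return ok_predict(tbl, variable, model, pts)[:2]
        if method.upper() == "COK":
            if lmc is None or covariate is None:
                raise ValueError("COK requires an LMC and a covariate name")
            return cok_predict(tbl, variable, covariate, lmc, pts)[:2]
        raise ValueError(f"unknown method {method!r}")

    if neighborhood == "all" or neighborhood >= n:
        est, var = predict(samples, centers)
    else:
        k = int(neighborhood)
        tree = cKDTree(sub[["x", "y"]].to_numpy(dtype=float))
        _, nbr = tree.query(centers, k=k)
        nbr = np.atleast_2d(nbr).reshape(len(centers), -1)
        est = np.empty(len(centers))
        var = np.empty(len(centers))
        # group cells sharing a neighbor set so each system is solved once
        sorted_all = np.sort(nbr, axis=1)
        order = np.lexsort(sorted_all.T)
        sorted_nbr = sorted_all[order]
        starts = np.flatnonzero(
            np.r_[True, np.any(sorted_nbr[1:] != sorted_nbr[:-1], axis=1)]
        )
        for s, e in zip(starts, np.r_[starts[1:], len(order)]):
            cells = order[s:e]
            keep = sub.iloc[sorted_nbr[s]]
            if method.upper() == "COK":
                # neighborhood restricts the target variable only; the
                # covariate stays fully available (heterotopic support)
                rest = samples.drop(index=keep.index).copy()
                rest[variable] = np.nan
                local = pd.concat([keep, rest])
            else:
                local = keep
            e_, v_ = predict(local, centers[cells])
            est[cells], var[cells] = e_, v_
    return PredictionGrid(spec, est, var, variable, method.upper())
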