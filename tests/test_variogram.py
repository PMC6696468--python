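"""Variogram estimators against literal pair enumeration, and model fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilkrige import (
    VariogramModel,
    empirical_cross_variogram,
    empirical_semivariogram,
    fit_lmc,
    fit_model,
    model_gamma,
)
from soilkrige.variogram import EmptyVariogramError, wls_objective

from conftest import line_samples


def brute_force_variogram(coords, za, zb, lag_width, n_lags, max_dist):
    """Literal O(n^2) enumeration of the (cross-)variogram estimator."""
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    dsums = np.zeros(n_lags)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d == 0.0 or d > max_dist:
                continue
            b = min(int(d // lag_width), n_lags - 1)
            counts[b] += 1
            sums[b] += (za[i] - za[j]) * (zb[i] - zb[j])
            dsums[b] += d
    keep = counts > 0
    return dsums[keep] / counts[keep], sums[keep] / (2.0 * counts[keep]), counts[keep]


class TestEmpiricalSemivariogram:
    def test_constant_field_is_zero(self):
        emp = empirical_semivariogram(line_samples([3.0] * 5), "v", lag_width=1.0,
                                      n_lags=5, max_dist=4.5)
        assert np.allclose(emp.semivariance, 0.0)

    def test_single_pair(self):
        emp = empirical_semivariogram(line_samples([0.0, 2.0]), "v", lag_width=1.0,
                                      n_lags=2, max_dist=1.5)
        assert emp.semivariance.tolist() == [2.0]
        assert emp.pair_counts.tolist() == [1]

    def test_collinear_alternating(self):
        # 6 pairs enumerated by hand: gamma(1)=0.5, gamma(2)=0, gamma(3)=0.5
        emp = empirical_semivariogram(line_samples([0.0, 1.0, 0.0, 1.0]), "v",
                                      lag_width=1.0, n_lags=4, max_dist=3.5)
        assert emp.lag_centers.tolist() == [1.0, 2.0, 3.0]
        assert emp.semivariance.tolist() == [0.5, 0.0, 0.5]
        assert emp.pair_counts.tolist() == [3, 2, 1]

    def test_all_pairs_beyond_max_dist(self):
        with pytest.raises(EmptyVariogramError):
            empirical_semivariogram(line_samples([0.0, 1.0]), "v", lag_width=0.1,
                                    n_lags=2, max_dist=0.5)

    @pytest.mark.parametrize("n", [5, 37, 200])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        coords = rng.uniform(0, 100, size=(n, 2))
        z = rng.normal(size=n)
        df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "v": z})
        emp = empirical_semivariogram(df, "v", lag_width=10.0, n_lags=8, max_dist=80.0)
        lags, gam, cnt = brute_force_variogram(coords, z, z, 10.0, 8, 80.0)
        assert np.allclose(emp.lag_centers, lags)
        assert np.allclose(emp.semivariance, gam)
        assert np.array_equal(emp.pair_counts, cnt)


class TestCrossVariogram:
    def _df(self):
        return pd.DataFrame({"x": [0.0, 1, 2], "y": 0.0,
                             "a": [0.0, 1, 2], "b": [0.0, 2, 4]})

    def test_enumerated_example(self):
        # lag-1 pairs (0,1),(1,2): (1*2 + 1*2)/4 = 1; lag-2 pair (0,2): 2*4/2 = 4
        emp = empirical_cross_variogram(self._df(), "a", "b", lag_width=1.0,
                                        n_lags=3, max_dist=2.5)
        assert emp.semivariance.tolist() == [1.0, 4.0]

    def test_self_cross_equals_direct(self, default_survey):
        direct = empirical_semivariogram(default_survey, "Cd_lab", n_lags=10)
        cross = empirical_cross_variogram(default_survey, "Cd_lab", "Cd_lab", n_lags=10)
        assert np.allclose(direct.semivariance, cross.semivariance)

    def test_constant_second_variable_is_zero(self):
        df = self._df()
        df["b"] = 7.0
        emp = empirical_cross_variogram(df, "a", "b", lag_width=1.0, n_lags=3,
                                        max_dist=2.5)
        assert np.allclose(emp.semivariance, 0.0)

    def test_symmetric_in_variable_order(self, default_survey):
        ab = empirical_cross_variogram(default_survey, "Cd_lab", "Cd_pxrf", n_lags=10)
        ba = empirical_cross_variogram(default_survey, "Cd_pxrf", "Cd_lab", n_lags=10)
        assert np.allclose(ab.semivariance, ba.semivariance)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n = 120
        coords = rng.uniform(0, 50, size=(n, 2))
        a, b = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "a": a, "b": b})
        emp = empirical_cross_variogram(df, "a", "b", lag_width=5.0, n_lags=8,
                                        max_dist=40.0)
        lags, gam, cnt = brute_force_variogram(coords, a, b, 5.0, 8, 40.0)
        assert np.allclose(emp.lag_centers, lags)
        assert np.allclose(emp.semivariance, gam)
        assert np.array_equal(emp.pair_counts, cnt)


class TestModelGamma:
    def test_zero_at_origin(self):
        for fam in ("spherical", "exponential", "gaussian"):
            m = VariogramModel(fam, 0.2, 0.8, 10.0)
            assert model_gamma(m, 0.0) == 0.0

    def test_spherical_sill_attained(self):
        m = VariogramModel("spherical", 0.2, 0.8, 10.0)
        assert model_gamma(m, 10.0) == pytest.approx(1.0)
        assert model_gamma(m, 25.0) == pytest.approx(1.0)

    def test_spherical_closed_form(self):
        m = VariogramModel("spherical", 0.0, 1.0, 2.0)
        assert model_gamma(m, 1.0) == pytest.approx(0.6875)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            model_gamma(VariogramModel("spherical", 0, 1, 1), -1.0)

    @settings(deadline=None, derandomize=True)
    @given(h=st.lists(st.floats(0, 100), min_size=2, max_size=20),
           fam=st.sampled_from(["spherical", "exponential"]))
    def test_monotone_nondecreasing(self, h, fam):
        m = VariogramModel(fam, 0.1, 0.9, 25.0)
        g = model_gamma(m, np.sort(np.asarray(h)))
        assert np.all(np.diff(g) >= -1e-12)


class TestFitModel:
    def test_noise_free_recovery(self):
        true = VariogramModel("spherical", 0.2, 0.8, 1500.0)
        h = np.linspace(100, 3000, 15)
        from soilkrige.variogram import EmpiricalVariogram

        emp = EmpiricalVariogram(h, model_gamma(true, h), np.full(15, 50), "v", "v")
        fit = fit_model(emp, family="spherical")
        assert fit.nugget == pytest.approx(0.2, rel=0.01)
        assert fit.partial_sill == pytest.approx(0.8, rel=0.01)
        assert fit.range_ == pytest.approx(1500.0, rel=0.01)

    def test_all_zero_degenerates(self):
        from soilkrige.variogram import EmpiricalVariogram

        emp = EmpiricalVariogram([1.0, 2, 3], [0.0, 0, 0], [5, 5, 5], "v", "v")
        fit = fit_model(emp)
        assert fit.nugget == 0.0 and fit.partial_sill == 0.0

    def test_too_few_lags_rejected(self):
        from soilkrige.variogram import EmpiricalVariogram

        emp = EmpiricalVariogram([1.0, 2], [0.5, 0.8], [5, 5], "v", "v")
        with pytest.raises(ValueError):
            fit_model(emp)

    def test_beats_grid_search_oracle(self):
        from soilkrige.variogram import EmpiricalVariogram

        rng = np.random.default_rng(2)
        true = VariogramModel("spherical", 0.3, 0.7, 800.0)
        h = np.linspace(50, 2000, 12)
        gam = model_gamma(true, h) * rng.uniform(0.85, 1.15, size=12)
        emp = EmpiricalVariogram(h, gam, np.full(12, 40), "v", "v")
        fit = fit_model(emp, family="spherical")
        best_grid = min(
            wls_objective(emp, VariogramModel("spherical", n, p, r))
            for n in np.linspace(0, 1.5, 20)
            for p in np.linspace(0, 1.5, 20)
            for r in np.linspace(50, 4000, 20)
        )
        assert wls_objective(emp, fit) <= best_grid + 1e-9


class TestFitLMC:
    def test_single_variable_reduces_to_direct_fit(self):
        from soilkrige.variogram import EmpiricalVariogram

        true = VariogramModel("spherical", 0.2, 0.8, 1000.0)
        h = np.linspace(100, 2000, 12)
        emp = EmpiricalVariogram(h, model_gamma(true, h), np.full(12, 30), "v", "v")
        lmc = fit_lmc({("v", "v"): emp}, [("nugget", 1.0), ("spherical", 1000.0)])
        assert lmc.matrices[0][0, 0] == pytest.approx(0.2, abs=0.01)
        assert lmc.matrices[1][0, 0] == pytest.approx(0.8, abs=0.01)
        assert np.allclose(lmc.gamma("v", "v", h), model_gamma(true, h), atol=0.01)

    def test_psd_projection(self):
        from soilkrige.variogram import EmpiricalVariogram

        h = np.linspace(1, 10, 8)
        cnt = np.full(8, 20)
        # cross-variogram larger than the direct sills forces a non-PSD raw fit
        ea = EmpiricalVariogram(h, np.full(8, 1.0), cnt, "a", "a")
        eb = EmpiricalVariogram(h, np.full(8, 1.0), cnt, "b", "b")
        ex = EmpiricalVariogram(h, np.full(8, 2.5), cnt, "a", "b")
        lmc = fit_lmc({("a", "a"): ea, ("b", "b"): eb, ("a", "b"): ex},
                      [("nugget", 1.0), ("spherical", 5.0)])
        for B in lmc.matrices:
            assert np.linalg.eigvalsh(B).min() >= -1e-8

    def test_missing_cross_rejected(self):
        from soilkrige.variogram import EmpiricalVariogram

        h = np.linspace(1, 10, 5)
        ea = EmpiricalVariogram(h, np.ones(5), np.full(5, 9), "a", "a")
        eb = EmpiricalVariogram(h, np.ones(5), np.full(5, 9), "b", "b")
        with pytest.raises(ValueError, match="cross"):
            fit_lmc({("a", "a"): ea, ("b", "b"): eb}, [("nugget", 1.0)])

    def test_intrinsic_correlation_recovery(self):
        """Known 2-variable intrinsic LMC (corr 0.8): cross/direct sill ratio
        recovered within 20% (median of 30 seeds, n=1000)."""
        from soilkrige.synthetic_data import _spatial_factor

        true = VariogramModel("spherical", 0.2, 0.8, 3000.0)
        rho = 0.8
        L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        ratios = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 20000, size=(1000, 2))
            A = _spatial_factor(coords, true)
            f = rng.standard_normal((1000, 2)) @ L.T
            df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                               "a": A @ f[:, 0], "b": A @ f[:, 1]})
            kw = dict(max_dist=8000.0, n_lags=16)
            lmc = fit_lmc(
                {
                    ("a", "a"): empirical_semivariogram(df, "a", **kw),
                    ("b", "b"): empirical_semivariogram(df, "b", **kw),
                    ("a", "b"): empirical_cross_variogram(df, "a", "b", **kw),
                },
                [("nugget", 1.0), ("spherical", 3000.0)],
            )
            denom = np.sqrt(lmc.direct_sill("a") * lmc.direct_sill("b"))
            ratios.append(lmc.cross_sill("a", "b") / denom)
        assert np.median(ratios) == pytest.approx(rho, rel=0.2)
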