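import json

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from darkfleet.models import (
    N_BINS,
    QuantileLine,
    Z_TWO_THIRDS,
    build_L,
    fit_detection_curve,
    fit_length_quantiles,
    load_models,
    lognormal_from_quantiles,
    plateau_rate,
    save_models,
)
from darkfleet.models import FittingError
from darkfleet.simulate import TrueDetectionCurve


def _census(rng, n=400, n_scenes=(7, 10), curve=None):
    curve = curve or TrueDetectionCurve()
    lengths = np.clip(rng.lognormal(np.log(35.0), 0.35, n), 12.0, 350.0)
    ns = rng.integers(*n_scenes, n)
    nd = rng.binomial(ns, curve.at(lengths))
    return pd.DataFrame({"length_m": lengths, "detection_fraction": nd / ns})


class TestDetectionCurve:
    def test_plateau_from_printed_counts(self):
        # 42 of 46 large vessels detected -> ~91%
        assert plateau_rate(42, 46) == pytest.approx(0.913, abs=5e-4)

    def test_all_detected_gives_unit_curve(self):
        rng = np.random.default_rng(0)
        lengths = np.concatenate([rng.uniform(15, 59, 30), rng.uniform(60, 120, 10)])
        rec = pd.DataFrame({"length_m": lengths, "detection_fraction": 1.0})
        curve = fit_detection_curve(rec)
        assert np.allclose(curve.alpha, 1.0, atol=1e-6)
        assert curve.plateau == pytest.approx(1.0)

    def test_recovers_generating_ramp(self):
        true = TrueDetectionCurve()
        rng = np.random.default_rng(5)
        curve = fit_detection_curve(_census(rng, n=500))
        for length in (20, 30, 40, 50, 58):
            assert curve.alpha[length] == pytest.approx(float(true.at(length)), abs=0.08)
        assert curve.plateau == pytest.approx(true.plateau, abs=0.06)

    def test_curve_is_monotone_below_knot_and_flat_above(self):
        rng = np.random.default_rng(6)
        curve = fit_detection_curve(_census(rng))
        below = curve.alpha[:60]
        assert (np.diff(below) >= -1e-12).all()
        assert np.allclose(curve.alpha[60:], curve.plateau)

    def test_insufficient_records_raise(self):
        rec = pd.DataFrame({"length_m": [20.0, 30.0], "detection_fraction": [0.5, 1.0]})
        with pytest.raises(FittingError):
            fit_detection_curve(rec)

    def test_invariant_bounds(self):
        rng = np.random.default_rng(7)
        curve = fit_detection_curve(_census(rng))
        assert (curve.alpha >= 0).all() and (curve.alpha <= 1).all()


class TestLengthQuantiles:
    def test_noiseless_pairs_give_identity_lines(self):
        x = np.linspace(15.0, 120.0, 60)
        pairs = pd.DataFrame({"true_length_m": x, "sar_length_m": x})
        q13, q23 = fit_length_quantiles(pairs)
        grid = np.linspace(20, 110, 10)
        assert np.allclose(q13.predict(grid), grid, atol=1e-3)
        assert np.allclose(q23.predict(grid), grid, atol=1e-3)

    def test_recovers_lognormal_sigma_from_quantile_gap(self):
        sigma = 0.2
        rng = np.random.default_rng(11)
        x = np.clip(rng.lognormal(np.log(40.0), 0.4, 3000), 15.0, 200.0)
        y = x * np.exp(rng.normal(0.0, sigma, x.size))
        q13, q23 = fit_length_quantiles(
            pd.DataFrame({"true_length_m": x, "sar_length_m": y})
        )
        at = 40.0
        _, sig_hat = lognormal_from_quantiles(
            float(q13.predict(at)), float(q23.predict(at))
        )
        assert sig_hat == pytest.approx(sigma, rel=0.15)

    def test_median_error_small_despite_high_variability(self):
        rng = np.random.default_rng(12)
        x = np.clip(rng.lognormal(np.log(40.0), 0.4, 2000), 15.0, 200.0)
        y = x * np.exp(rng.normal(0.0, 0.2, x.size))
        q13, q23 = fit_length_quantiles(
            pd.DataFrame({"true_length_m": x, "sar_length_m": y})
        )
        # the two quantile lines straddle the identity without gross bias
        mid = 0.5 * (q13.predict(40.0) + q23.predict(40.0))
        assert float(mid) == pytest.approx(40.0, rel=0.1)

    def test_too_few_or_too_narrow_pairs_raise(self):
        x = np.linspace(30, 40, 25)
        with pytest.raises(FittingError):
            fit_length_quantiles(pd.DataFrame({"true_length_m": x, "sar_length_m": x}))
        x = np.linspace(10, 100, 10)
        with pytest.raises(FittingError):
            fit_length_quantiles(pd.DataFrame({"true_length_m": x, "sar_length_m": x}))

    def test_quantile_order_preserved_over_data_range(self):
        rng = np.random.default_rng(13)
        x = np.clip(rng.lognormal(np.log(40.0), 0.4, 500), 15.0, 200.0)
        y = x * np.exp(rng.normal(0.0, 0.25, x.size))
        q13, q23 = fit_length_quantiles(
            pd.DataFrame({"true_length_m": x, "sar_length_m": y})
        )
        grid = np.linspace(x.min(), x.max(), 50)
        assert (q23.predict(grid) >= q13.predict(grid)).all()


class TestLognormalFromQuantiles:
    def test_degenerate_quantiles_give_point_mass(self):
        mu, sigma = lognormal_from_quantiles(40.0, 40.0)
        assert mu == pytest.approx(np.log(40.0))
        assert sigma == 0.0

    def test_against_numeric_inversion_oracle(self):
        # independently solve for (mu, sigma) whose lognormal has the
        # requested 1/3 and 2/3 quantiles
        def system(params):
            mu, sigma = params
            return [
                stats.lognorm.ppf(1 / 3, s=sigma, scale=np.exp(mu)) - 30.0,
                stats.lognorm.ppf(2 / 3, s=sigma, scale=np.exp(mu)) - 50.0,
            ]

        oracle = optimize.fsolve(system, x0=[np.log(40.0), 0.3])
        mu, sigma = lognormal_from_quantiles(30.0, 50.0)
        assert mu == pytest.approx(oracle[0], abs=1e-8)
        assert sigma == pytest.approx(oracle[1], abs=1e-8)

    def test_round_trip(self):
        mu, sigma = lognormal_from_quantiles(30.0, 50.0)
        assert stats.lognorm.ppf(1 / 3, s=sigma, scale=np.exp(mu)) == pytest.approx(30.0, abs=1e-9)
        assert stats.lognorm.ppf(2 / 3, s=sigma, scale=np.exp(mu)) == pytest.approx(50.0, abs=1e-9)

    def test_invalid_quantiles_raise(self):
        with pytest.raises(ValueError):
            lognormal_from_quantiles(-1.0, 10.0)
        with pytest.raises(ValueError):
            lognormal_from_quantiles(50.0, 30.0)


def _sigma_lines(sigma):
    z = Z_TWO_THIRDS
    q13 = QuantileLine(coefs=np.array([0.0, np.exp(-z * sigma)]), tau=1 / 3)
    q23 = QuantileLine(coefs=np.array([0.0, np.exp(z * sigma)]), tau=2 / 3)
    return q13, q23


class TestBuildL:
    def test_zero_sigma_is_binned_identity(self):
        q13, q23 = _sigma_lines(0.0)
        L = build_L(q13, q23).L
        assert np.allclose(L, np.eye(N_BINS))

    def test_columns_are_stochastic(self):
        L = build_L(*_sigma_lines(0.2)).L
        assert np.allclose(L.sum(axis=0), 1.0, atol=1e-6)
        assert (L >= 0).all()

    def test_column_mode_near_lognormal_mode(self):
        sigma = 0.15
        L = build_L(*_sigma_lines(sigma)).L
        for j in (50, 100, 200):
            mu = np.log(j + 0.5)
            mode = np.exp(mu - sigma**2)
            assert abs(int(np.argmax(L[:, j])) + 0.5 - mode) < 3.0


class TestSerialization:
    def test_models_round_trip(self, tmp_path):
        rng = np.random.default_rng(20)
        curve = fit_detection_curve(_census(rng))
        q13, q23 = _sigma_lines(0.2)
        lmat = build_L(q13, q23)
        path = tmp_path / "models.json"
        save_models(path, curve, lmat)
        curve2, lmat2 = load_models(path)
        assert np.allclose(curve.alpha, curve2.alpha)
        assert curve2.plateau == curve.plateau
        assert np.allclose(lmat.L, lmat2.L)

    def test_bad_version_refused(self, tmp_path):
        path = tmp_path / "models.json"
        path.write_text(json.dumps({"version": 99}))
        with pytest.raises(ValueError):
            load_models(path)
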