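import numpy as np
import pandas as pd
import pytest

from darkfleet.estimator import (
    LengthHistogram,
    UnidentifiableError,
    bootstrap_uncertainty,
    estimate,
    forward,
    objective,
    scale_to_fishing,
)
from darkfleet.models import N_BINS, DetectionCurve, LengthErrorMatrix, QuantileLine, Z_TWO_THIRDS, build_L
from darkfleet.simulate import TrueDetectionCurve


def _hist(bins, role="observed"):
    counts = np.zeros(N_BINS)
    for b, c in bins.items():
        counts[b] = c
    return LengthHistogram(counts=counts, role=role)


def _unit_alpha():
    return DetectionCurve(alpha=np.ones(N_BINS), plateau=1.0)


def _identity_L():
    return LengthErrorMatrix(L=np.eye(N_BINS))


def _sigma_L(sigma):
    z = Z_TWO_THIRDS
    q13 = QuantileLine(coefs=np.array([0.0, np.exp(-z * sigma)]), tau=1 / 3)
    q23 = QuantileLine(coefs=np.array([0.0, np.exp(z * sigma)]), tau=2 / 3)
    return build_L(q13, q23)


def _ramp_alpha():
    t = TrueDetectionCurve()
    return DetectionCurve(alpha=np.minimum(t.at(np.arange(N_BINS) + 0.5), 1.0), plateau=t.plateau)


class TestForward:
    def test_identity_observation_model_is_identity(self):
        l_a = _hist({30: 5, 45: 2}, role="all")
        l_e = forward(l_a, _unit_alpha(), _identity_L())
        assert np.array_equal(l_e.counts, l_a.counts)

    def test_zero_detectability_sees_nothing(self):
        alpha = DetectionCurve(alpha=np.zeros(N_BINS), plateau=0.0)
        l_e = forward(_hist({30: 5}), alpha, _identity_L())
        assert l_e.T == 0.0

    def test_count_conservation_is_exact(self):
        rng = np.random.default_rng(3)
        raw = rng.random((N_BINS, N_BINS))
        L = LengthErrorMatrix(L=raw / raw.sum(axis=0, keepdims=True))
        alpha = DetectionCurve(alpha=rng.random(N_BINS))
        l_a = LengthHistogram(rng.random(N_BINS) * 10, role="all")
        l_e = forward(l_a, alpha, L)
        assert l_e.T == pytest.approx(float((alpha.alpha * l_a.counts).sum()), abs=1e-9)


class TestObjective:
    def test_zero_iff_identical(self):
        h = _hist({30: 4, 40: 6})
        assert objective(h, h) == 0.0

    def test_total_mismatch_alone_costs_its_square(self):
        a = _hist({30: 4, 40: 4})
        b = _hist({30: 4.5, 40: 4.5})
        # same shape: KS term 0, totals differ by 1
        assert objective(a, b) == pytest.approx(1.0)

    def test_three_bin_case_matches_cumulative_oracle(self):
        a = _hist({0: 2, 1: 1, 2: 1})
        b = _hist({0: 1, 1: 1, 2: 2})

        def oracle(x, y):
            dx = x / x.sum()
            dy = y / y.sum()
            ks = max(abs(np.cumsum(dx) - np.cumsum(dy)))
            return ks + (x.sum() - y.sum()) ** 2

        assert objective(a, b) == pytest.approx(oracle(a.counts, b.counts))
        assert objective(a, b) == pytest.approx(0.25)

    def test_non_negative(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = LengthHistogram(rng.random(N_BINS))
            b = LengthHistogram(rng.random(N_BINS))
            assert objective(a, b) >= 0.0


class TestEstimate:
    def test_perfect_observation_model_returns_observations(self):
        l_o = _hist({30: 10, 31: 10, 32: 10, 33: 10, 34: 10})
        est = estimate(l_o, _unit_alpha(), _identity_L(), seed=0)
        assert est.objective_value < 1e-9
        assert est.total == pytest.approx(50.0, rel=0.01)

    def test_empty_observation_gives_zero(self):
        est = estimate(_hist({}), _unit_alpha(), _identity_L(), seed=0)
        assert est.total == 0.0

    def test_recovery_through_thinning_and_smearing(self):
        # block-constant truth pushed through the forward model, no noise
        truth = np.zeros(N_BINS)
        truth[25:50] = 4.0
        truth[50:70] = 2.0
        alpha = _ramp_alpha()
        L = _sigma_L(0.15)
        l_o = forward(LengthHistogram(truth, role="all"), alpha, L)
        est = estimate(LengthHistogram(l_o.counts, role="observed"), alpha, L, seed=1)
        assert est.total == pytest.approx(truth.sum(), rel=0.1)

    def test_halving_detectability_doubles_the_estimate(self):
        alpha = _ramp_alpha()
        half = DetectionCurve(alpha=alpha.alpha / 2.0, plateau=alpha.plateau / 2)
        truth = np.zeros(N_BINS)
        truth[30:60] = 3.0
        l_o = forward(LengthHistogram(truth, role="all"), alpha, _identity_L())
        l_o = LengthHistogram(l_o.counts, role="observed")
        t_full = estimate(l_o, alpha, _identity_L(), seed=2).total
        t_half = estimate(l_o, half, _identity_L(), seed=2).total
        assert t_half / t_full == pytest.approx(2.0, rel=0.1)

    def test_more_detections_never_lower_the_estimate(self):
        alpha = _ramp_alpha()
        L = _sigma_L(0.2)
        base = _hist({30: 5, 40: 5, 50: 5})
        more = _hist({30: 8, 40: 8, 50: 8, 35: 4})
        t1 = estimate(base, alpha, L, seed=3).total
        t2 = estimate(more, alpha, L, seed=3).total
        assert t2 >= t1 * 0.99

    def test_unreachable_observed_bins_are_an_error(self):
        alpha = DetectionCurve(alpha=np.where(np.arange(N_BINS) >= 30, 0.5, 0.0))
        with pytest.raises(UnidentifiableError):
            estimate(_hist({10: 3}), alpha, _identity_L(), seed=0)

    def test_seeded_determinism(self):
        alpha = _ramp_alpha()
        L = _sigma_L(0.2)
        l_o = _hist({25: 3, 33: 6, 47: 4})
        a = estimate(l_o, alpha, L, seed=9)
        b = estimate(l_o, alpha, L, seed=9)
        assert np.array_equal(a.l_A_hat.counts, b.l_A_hat.counts)


class TestScaleToFishing:
    def test_all_fishing_census(self):
        census = pd.DataFrame({"vclass": ["drifting_longline"] * 5, "length_m": [30.0] * 5})
        assert scale_to_fishing(100.0, census) == pytest.approx(100.0)

    def test_half_fishing_census(self):
        census = pd.DataFrame(
            {"vclass": ["drifting_longline", "cargo_or_tanker"] * 5, "length_m": [30.0] * 10}
        )
        assert scale_to_fishing(100.0, census) == pytest.approx(50.0)

    def test_only_small_vessels_enter_the_share(self):
        census = pd.DataFrame(
            {
                "vclass": ["drifting_longline", "cargo_or_tanker"],
                "length_m": [30.0, 150.0],   # the carrier is above 60 m
            }
        )
        assert scale_to_fishing(100.0, census) == pytest.approx(100.0)

    def test_regional_share_example(self):
        # an 83% fishing share, as in a longline-dominated census
        vclasses = ["drifting_longline"] * 83 + ["cargo_or_tanker"] * 17
        census = pd.DataFrame({"vclass": vclasses, "length_m": [30.0] * 100})
        assert scale_to_fishing(172.0, census) == pytest.approx(0.83 * 172.0)

    def test_empty_census_raises(self):
        with pytest.raises(ValueError):
            scale_to_fishing(10.0, pd.DataFrame(columns=["vclass", "length_m"]))


class TestBootstrap:
    def _noise_free_world(self, rng, n=120):
        lengths = np.concatenate(
            [rng.uniform(15.0, 59.0, int(n * 0.8)), rng.uniform(60.0, 150.0, n - int(n * 0.8))]
        )
        ns = rng.integers(3, 7, n)
        vessels = pd.DataFrame(
            {
                "vessel_id": [f"v{i}" for i in range(n)],
                "length_m": lengths,
                "n_scenes": ns,
                "n_detected": ns,  # every instance detected
            }
        )
        pairs = pd.DataFrame(
            {
                "vessel_id": np.repeat(vessels["vessel_id"], ns),
                "true_length_m": np.repeat(lengths, ns),
                "sar_length_m": np.repeat(lengths, ns),  # sigma = 0
            }
        )
        return vessels, pairs

    def test_zero_noise_world_has_near_zero_error(self):
        rng = np.random.default_rng(21)
        vessels, pairs = self._noise_free_world(rng)
        res = bootstrap_uncertainty(vessels, pairs, n_experiments=15, seed=5)
        assert res.mape < 0.05
        assert res.n_experiments > 0

    def test_interval_multipliers_are_ordered(self):
        rng = np.random.default_rng(22)
        vessels, pairs = self._noise_free_world(rng)
        res = bootstrap_uncertainty(vessels, pairs, n_experiments=15, seed=6)
        lo, hi = res.ci90_multipliers
        assert lo <= hi
        ci = res.dress(100.0)
        assert ci[0] <= ci[1]

    def test_too_few_vessels_raise(self):
        vessels = pd.DataFrame(
            {"vessel_id": ["a"], "length_m": [30.0], "n_scenes": [1], "n_detected": [1]}
        )
        with pytest.raises(ValueError):
            bootstrap_uncertainty(vessels, pd.DataFrame(columns=["vessel_id", "true_length_m", "sar_length_m"]), 5)
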