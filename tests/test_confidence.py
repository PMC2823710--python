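import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from samplex.confidence import (
    Calibration,
    DegenerateDataError,
    SubsetStats,
    attribute_confidences,
    calibrate_extremes,
    gamma,
    k_factor,
    starting_confidences,
)
from samplex.core import PerResidueData, ResidueKey, SamplexParams


def data_from(values):
    return PerResidueData(values={ResidueKey("A", i + 1): float(v) for i, v in enumerate(values)})


class TestKFactor:
    def test_value_at_mean_gives_zero(self):
        stats = k_factor(3.0, [1, 3, 5])
        assert stats.k == pytest.approx(0.0)

    def test_uniform_subset_is_degenerate(self):
        stats = k_factor(2.0, [2, 2, 2])
        assert stats.degenerate

    def test_population_sigma_oracle(self):
        # subset {1..5}: population sigma = sqrt(2), value 5 -> k = 2/sqrt(2)
        stats = k_factor(5.0, [1, 2, 3, 4, 5])
        assert stats.k == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            k_factor(1.0, [])


class TestGamma:
    CAL = Calibration(k_high=2.0, k_low=-1.0)

    def _stats(self, k):
        return SubsetStats(mu=0.0, sigma=1.0, k=k, degenerate=False)

    def test_degenerate_contributes_zero(self):
        assert gamma(SubsetStats(0, 0, float("nan"), True), self.CAL) == 0.0

    @pytest.mark.parametrize(
        "k, expected",
        [(2.0, 1.0), (-1.0, -1.0), (5.0, 1.0), (-4.0, -1.0), (1.0, 0.5), (-0.5, -0.5), (0.0, 0.0)],
    )
    def test_piecewise_linear_clipped(self, k, expected):
        assert gamma(self._stats(k), self.CAL) == pytest.approx(expected)


class TestCalibration:
    def test_deterministic_dataset(self, nine_zeros_one_one, rng):
        # every subset is {1, 0, 0}: k_high and k_low have closed forms
        params = SamplexParams(calib_multiplier=10)
        calib = calibrate_extremes(nine_zeros_one_one, params, rng)
        sigma = math.sqrt(2.0 / 9.0)
        assert calib.k_high == pytest.approx((1 - 1 / 3) / sigma, abs=1e-12)  # 1.41421
        assert calib.k_low == pytest.approx((0 - 1 / 3) / sigma, abs=1e-12)  # -0.70711

    def test_too_few_values_raises(self, rng):
        with pytest.raises(ValueError):
            calibrate_extremes(data_from([0, 1]), SamplexParams(), rng)

    def test_all_equal_raises(self, rng):
        with pytest.raises(DegenerateDataError):
            calibrate_extremes(data_from([2, 2, 2, 2]), SamplexParams(), rng)

    def test_scale_invariance(self, rng):
        vals = [0.1, 0.4, 0.2, 0.9, 0.05, 0.3, 0.7, 0.15, 0.6, 0.25]
        p = SamplexParams(calib_multiplier=50)
        c1 = calibrate_extremes(data_from(vals), p, np.random.default_rng(3))
        c2 = calibrate_extremes(data_from([10 * v for v in vals]), p, np.random.default_rng(3))
        assert c1.k_high == pytest.approx(c2.k_high, rel=1e-9)
        assert c1.k_low == pytest.approx(c2.k_low, rel=1e-9)


class TestAttribution:
    def test_max_residue_reaches_plus_one_exactly(self, nine_zeros_one_one):
        rng = np.random.default_rng(1)
        conf, _ = starting_confidences(
            nine_zeros_one_one, SamplexParams(calib_multiplier=10, trial_multiplier=20), rng
        )
        assert conf.rho[ResidueKey("A", 10)] == 1.0

    def test_zero_residue_matches_hypergeometric_expectation(self, nine_zeros_one_one):
        # a zero's subset is {0,0,0} (Gamma 0, prob 7/9) or {0,0,1} (k = k_low,
        # Gamma -1, prob 2/9): E[rho] = -2/9, checked at n_trial = 1000
        rng = np.random.default_rng(0)
        conf, _ = starting_confidences(
            nine_zeros_one_one, SamplexParams(calib_multiplier=10, trial_multiplier=100), rng
        )
        assert conf.rho[ResidueKey("A", 1)] == pytest.approx(-2 / 9, abs=0.02)

    def test_all_confidences_in_unit_interval(self, rng):
        data = data_from([0.1, 0.5, 0.2, 0.8, 0.3, 0.05, 0.6, 0.4, 0.9, 0.7])
        conf, _ = starting_confidences(data, SamplexParams(calib_multiplier=20, trial_multiplier=20), rng)
        assert all(-1.0 <= r <= 1.0 for r in conf.rho.values())

    def test_global_extremes_attain_extreme_rho(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.abs(rng.normal(0.3, 0.25, size=12))
            data = data_from(vals)
            conf, _ = starting_confidences(
                data, SamplexParams(calib_multiplier=10, trial_multiplier=10), np.random.default_rng(seed)
            )
            keys = list(data.values)
            rho = np.array([conf.rho[k] for k in keys])
            assert rho[int(np.argmax(vals))] == rho.max()
            assert rho[int(np.argmin(vals))] == rho.min()

    @given(st.floats(min_value=0.01, max_value=100), st.integers(min_value=0, max_value=5))
    def test_rho_invariant_under_positive_scaling(self, scale, seed):
        vals = [0.1, 0.4, 0.2, 0.9, 0.05, 0.3, 0.7, 0.15]
        p = SamplexParams(calib_multiplier=10, trial_multiplier=10)
        c1, _ = starting_confidences(data_from(vals), p, np.random.default_rng(seed))
        c2, _ = starting_confidences(
            data_from([scale * v for v in vals]), p, np.random.default_rng(seed)
        )
        for k in c1.rho:
            assert c1.rho[k] == pytest.approx(c2.rho[k], abs=1e-9)

    def test_identical_seed_reproduces_bit_for_bit(self):
        data = data_from([0.1, 0.5, 0.2, 0.8, 0.3, 0.05, 0.6, 0.4])
        p = SamplexParams(calib_multiplier=10, trial_multiplier=10, seed=42)
        runs = [
            starting_confidences(data, p, np.random.default_rng(42))[0].rho for _ in range(2)
        ]
        assert runs[0] == runs[1]
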