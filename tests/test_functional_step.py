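"""TSG-S / OG-S scoring, threshold calibration and cohort rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverscope import (
    background_trunc_ratio,
    calibrate_thresholds,
    og_score,
    rescale_thresholds,
    tsg_score,
)
from driverscope.functional_step import cohort_scale_factor, kernel_density
from driverscope.maf_io import PatientProfile


def _binom_tail_oracle(k, n, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestTsgScore:
    def test_zero_truncating_scores_zero(self):
        assert tsg_score(0, 10, 0.14) == 0.0

    def test_all_truncating_closed_form(self):
        assert tsg_score(7, 7, 0.2) == pytest.approx(-7 * math.log10(0.2), rel=1e-12)

    @pytest.mark.parametrize("k,n,p0", [(5, 10, 0.14), (2, 8, 0.3), (12, 30, 0.1)])
    def test_matches_pmf_summation(self, k, n, p0):
        assert tsg_score(k, n, p0) == pytest.approx(
            -math.log10(_binom_tail_oracle(k, n, p0)), rel=1e-9
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 40), p0=st.floats(0.01, 0.9))
    def test_monotone_in_k_and_p0(self, n, p0):
        scores = [tsg_score(k, n, p0) for k in range(n + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
        k = n // 2
        assert tsg_score(k, n, p0) + 1e-12 >= tsg_score(k, n, min(0.95, p0 + 0.05))

    def test_rejects_bad_p0(self):
        with pytest.raises(ValueError):
            tsg_score(1, 2, 0.0)


class TestBackgroundRatio:
    def _profiles(self, specs):
        return {
            s: PatientProfile(sample=s, n_truncating=t, n_missense=m, n_silent=sl)
            for s, (t, m, sl) in specs.items()
        }

    def test_identical_ratios_give_that_ratio(self):
        prof = self._profiles({"A": (2, 6, 2), "B": (4, 12, 4), "C": (1, 3, 1)})
        assert background_trunc_ratio(prof, {"A", "B", "C"}) == pytest.approx(0.2)

    def test_zero_ratio_clipped_at_floor(self):
        prof = self._profiles({"A": (0, 5, 5)})
        assert background_trunc_ratio(prof, {"A"}) == pytest.approx(1e-4)

    def test_three_carrier_weighted_mean(self):
        # carriers A (10 muts, ratio .5), B (40 muts, ratio .1); cohort also C (ratio .2, 10 muts)
        prof = self._profiles({"A": (5, 3, 2), "B": (4, 30, 6), "C": (2, 4, 4)})
        cohort_mean = np.mean([0.5, 0.1, 0.2])
        wa, wb = 10 / 30, 40 / 60
        expected = np.mean(
            [wa * 0.5 + (1 - wa) * cohort_mean, wb * 0.1 + (1 - wb) * cohort_mean]
        )
        got = background_trunc_ratio(prof, {"A", "B"}, shrinkage_k=20.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_carriers_raises(self):
        with pytest.raises(ValueError):
            background_trunc_ratio({}, {"A"})


class TestOgScore:
    def test_density_normalized(self):
        d = kernel_density([5, 50, 95], [1.0, 2.0, 0.5], 100, 4.0)
        assert d.sum() == pytest.approx(1.0, abs=1e-9)
        assert (d >= 0).all()

    def test_single_hotspot_beats_spread(self):
        clustered = og_score([50] * 6, None, 100, seed=5)
        spread = og_score([10, 25, 40, 60, 80, 95], None, 100, seed=5)
        assert clustered > 0
        assert clustered > spread

    def test_two_identical_vs_separated(self):
        same = og_score([50, 50], None, 100, seed=5)
        apart = og_score([1, 100], None, 100, seed=5)
        assert same > apart

    def test_uniform_positions_score_near_zero(self):
        rng = np.random.default_rng(123)
        scores = [
            og_score(rng.integers(1, 201, size=8), None, 200, seed=int(s), n_reps=500)
            for s in rng.integers(0, 2**31, size=20)
        ]
        assert abs(np.mean(scores)) < 1.0
        assert all(abs(s) < 3 for s in scores)

    def test_translation_invariance_away_from_edges(self):
        a = og_score([80, 82, 85, 90], None, 300, seed=9, n_reps=2000)
        b = og_score([180, 182, 185, 190], None, 300, seed=9, n_reps=2000)
        assert a == pytest.approx(b, abs=0.05)

    def test_seed_determinism_and_degenerate_cases(self):
        args = ([10, 20, 20, 90], [1.0, 2.0, 1.0, 0.5], 120)
        assert og_score(*args, seed=7) == og_score(*args, seed=7)
        assert og_score([5], None, 100) == 0.0  # one mutation: no information
        with pytest.raises(ValueError):
            og_score([1, 1], None, 1)

    def test_spreading_fixed_mass_decreases_score(self):
        # M=10 on L=200: from one residue to evenly spaced, strictly less clustered
        scores = []
        for s in range(0, 22, 2):
            pos = [int(round(100 + s * (i - 4.5))) for i in range(10)]
            scores.append(og_score(pos, None, 200, seed=11, n_reps=1000))
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestCalibration:
    def test_perfect_separation_has_mcc_one(self):
        scores = [("a", 0.1), ("b", 0.2), ("c", 5.0), ("d", 6.0)]
        t, mcc = calibrate_thresholds(scores, {"c", "d"})
        assert mcc == pytest.approx(1.0)
        assert t == 5.0

    def test_matches_brute_force_scan(self):
        # 6-gene worked example, 2 positives
        scores = [("g1", 0.5), ("g2", 1.1), ("g3", 2.0), ("g4", 2.5), ("g5", 3.0), ("g6", 0.9)]
        positives = {"g4", "g5"}
        from sklearn.metrics import matthews_corrcoef

        y = [g in positives for g, _ in scores]
        best = max(
            sorted({s for _, s in scores}, reverse=True),
            key=lambda t: (matthews_corrcoef(y, [s >= t for _, s in scores]), t),
        )
        t, _ = calibrate_thresholds(scores, positives)
        assert t == best == 2.5

    def test_label_independent_scores_give_low_mcc(self):
        rng = np.random.default_rng(0)
        scores = [(f"g{i}", float(rng.random())) for i in range(200)]
        positives = {f"g{i}" for i in rng.choice(200, size=40, replace=False)}
        _, mcc = calibrate_thresholds(scores, positives)
        assert mcc < 0.35  # max over the scan of a null MCC curve stays small

    def test_degenerate_labels_fatal(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([("a", 1.0), ("b", 2.0)], {"a", "b"})


class TestRescaling:
    def test_reference_cohort_keeps_base(self):
        th = rescale_thresholds(3.0, 2.0, n_samples=200, median_mutations=40.0)
        assert th.tsg_eff == pytest.approx(3.0)
        assert th.og_eff == pytest.approx(2.0)

    def test_tiny_cohort_clips_at_floor_unless_lax(self):
        strict = rescale_thresholds(3.0, 2.0, n_samples=4, median_mutations=40.0)
        assert strict.tsg_eff == pytest.approx(0.25 * 3.0)
        lax = rescale_thresholds(3.0, 2.0, n_samples=4, median_mutations=40.0, lax=True)
        assert lax.tsg_eff < strict.floor_tsg
        assert lax.lax

    def test_scale_factor_monotone(self):
        assert cohort_scale_factor(50, 40) <= cohort_scale_factor(100, 40)
        assert cohort_scale_factor(100, 20) <= cohort_scale_factor(100, 60)
        with pytest.raises(ValueError):
            cohort_scale_factor(0, 40)
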