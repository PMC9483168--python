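"""%DR scoring: per-segment t-tests, weighted final score, responder classes."""

import math

import numpy as np
import pytest
from scipy import stats

from flimdr import (
    AcquisitionConfig,
    FractionalDistribution,
    RunConfig,
    TimepointScore,
    assess_case,
    per_bin_ttest,
    percent_dr,
    score_timepoint,
    shifted_experiment_spec,
    simulate_experiment,
    stratify,
    weighted_final,
)
from flimdr.errors import (
    ConfigError,
    DomainError,
    EmptyImageError,
    InsufficientReplicatesError,
)


def pooled_t_pvalue(a, b):
    """Independent textbook pooled-variance two-sample t-test (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 = ss / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * stats.t.sf(abs(t), na + nb - 2)


class TestPerBinTTest:
    def test_matches_textbook_pooled_t_on_random_tables(self, rng):
        for _ in range(20):
            nc, nt = rng.integers(2, 10, size=2)
            control = rng.normal(0.2, 0.05, size=(nc, 30))
            treated = rng.normal(0.22, 0.05, size=(nt, 30))
            p, _ = per_bin_ttest(control, treated)
            expected = [
                pooled_t_pvalue(control[:, j], treated[:, j]) for j in range(30)
            ]
            np.testing.assert_allclose(p, expected, atol=1e-10)

    def test_separated_heights_are_significant(self):
        control = np.array([[0.10], [0.12], [0.11], [0.09]])
        treated = np.array([[0.30], [0.32], [0.31], [0.29]])
        p, sig = per_bin_ttest(control, treated, alpha=0.05)
        assert sig[0]
        assert p[0] == pytest.approx(pooled_t_pvalue(control[:, 0], treated[:, 0]), abs=1e-10)

    def test_identical_arms_have_no_significant_bins(self):
        heights = np.tile([0.2, 0.3, 0.5], (4, 1))
        p, sig = per_bin_ttest(heights, heights)
        assert not sig.any()
        np.testing.assert_array_equal(p, 1.0)

    def test_all_zero_bin_gets_p_one(self):
        control = np.zeros((3, 2))
        control[:, 1] = [0.1, 0.2, 0.15]
        treated = np.zeros((3, 2))
        treated[:, 1] = [0.1, 0.2, 0.15]
        p, sig = per_bin_ttest(control, treated)
        assert p[0] == 1.0 and not sig[0]

    def test_zero_variance_unequal_means_is_significant(self):
        control = np.full((3, 1), 0.1)
        treated = np.full((3, 1), 0.4)
        p, sig = per_bin_ttest(control, treated)
        assert p[0] == 0.0 and sig[0]

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            per_bin_ttest(np.ones((1, 5)), np.ones((4, 5)))

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ConfigError):
            per_bin_ttest(np.ones((3, 5)), np.ones((3, 6)))


def _dist(heights):
    h = np.asarray(heights, dtype=float)
    edges = np.linspace(0, 1, len(h) + 1)
    return FractionalDistribution(heights=h, bin_edges=edges, n_pixels=100)


class TestPercentDR:
    def test_empty_mask_is_zero(self):
        assert percent_dr(_dist([0.25] * 4), np.zeros(4, bool)) == 0.0

    def test_full_mask_is_hundred(self):
        assert percent_dr(_dist([0.1, 0.9]), np.ones(2, bool)) == 100.0

    def test_toy_four_bin_example(self):
        mask = np.array([False, False, True, True])
        assert percent_dr(_dist([0.1, 0.2, 0.3, 0.4]), mask) == pytest.approx(70.0)

    def test_zero_curve_rejected(self):
        with pytest.raises(EmptyImageError):
            percent_dr(_dist([0.0, 0.0]), np.ones(2, bool))

    def test_mask_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            percent_dr(_dist([1.0]), np.ones(3, bool))


class TestWeightedFinal:
    def test_constant_input_is_identity(self):
        assert weighted_final({"24h": 10, "48h": 10, "72h": 10}) == pytest.approx(10)

    def test_worked_example_single_active_timepoint(self):
        assert weighted_final({"24h": 0, "48h": 0, "72h": 60}) == pytest.approx(30.0)

    def test_missing_timepoint_renormalizes_weights(self):
        assert weighted_final({"24h": 40, "72h": 80}) == pytest.approx(70.0)

    def test_result_bounded_by_inputs(self, rng):
        for _ in range(20):
            vals = dict(zip(("24h", "48h", "72h"), rng.uniform(0, 100, 3)))
            final = weighted_final(vals)
            assert min(vals.values()) <= final <= max(vals.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            weighted_final({})

    def test_missing_72h_rejected(self):
        with pytest.raises(ConfigError):
            weighted_final({"24h": 10.0})


class TestStratify:
    @pytest.mark.parametrize(
        "value, cls, binary",
        [
            (0.0, "NR", "Non-Resp"),
            (4.99, "NR", "Non-Resp"),
            (5.0, "LR", "Resp"),
            (19.99, "LR", "Resp"),
            (20.0, "MR", "Resp"),
            (49.99, "MR", "Resp"),
            (50.0, "HR", "Resp"),
            (92.0, "HR", "Resp"),
            (100.0, "HR", "Resp"),
        ],
    )
    def test_class_boundaries(self, value, cls, binary):
        assert stratify(value) == (cls, binary)

    def test_partition_is_total_and_single_valued(self):
        grid = np.linspace(0, 100, 4001)
        classes = [stratify(v)[0] for v in grid]
        assert set(classes) == {"NR", "LR", "MR", "HR"}
        # monotone: class index never decreases along the grid
        order = {"NR": 0, "LR": 1, "MR": 2, "HR": 3}
        idx = [order[c] for c in classes]
        assert all(a <= b for a, b in zip(idx, idx[1:]))

    @pytest.mark.parametrize("bad", [-0.1, 100.1, np.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DomainError):
            stratify(bad)


def _score(tp, pct):
    return TimepointScore(
        timepoint=tp, p_values=np.ones(4), significant_mask=np.zeros(4, bool),
        pct_dr=pct, n_control=8, n_treated=8,
    )


class TestAssessCase:
    def test_all_zero_scores_give_nr(self):
        a = assess_case([_score(tp, 0.0) for tp in ("24h", "48h", "72h")])
        assert a.final_pct_dr == 0.0
        assert a.responder_class == "NR" and a.responder_binary == "Non-Resp"

    def test_weighted_average_of_printed_per_timepoint_values(self):
        # 24 h and 72 h are observed per-timepoint values for a responsive case;
        # the 48 h value is a synthetic placeholder
        a = assess_case([_score("24h", 59.3), _score("48h", 0.0), _score("72h", 90.9)])
        assert a.final_pct_dr == pytest.approx((59.3 + 3 * 90.9) / 6, abs=1e-9)
        assert a.responder_class == "HR"

    def test_single_72h_score_drops_other_weights(self):
        a = assess_case([_score("72h", 4.0)])
        assert a.final_pct_dr == pytest.approx(4.0)
        assert a.responder_class == "NR"

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(ConfigError):
            assess_case([_score("72h", 1.0), _score("72h", 2.0)])

    def test_no_scores_rejected(self):
        with pytest.raises(ConfigError):
            assess_case([])


class TestScoreTimepoint:
    def test_treated_identical_to_control_scores_zero(self, config):
        acq = AcquisitionConfig(n_time_bins=64)
        spec = shifted_experiment_spec(
            shift=0.0, n_replicates=3, image_shape=(8, 8),
            photons_per_pixel=500.0, acquisition=acq, seed=9,
        )
        controls, _ = simulate_experiment(spec).arms("72h")
        cfg = RunConfig(acquisition=acq)
        score = score_timepoint(controls, controls, cfg)
        assert score.pct_dr == 0.0
        assert not score.significant_mask.any()

    def test_strong_shift_scores_above_fifty(self, config):
        acq = AcquisitionConfig(n_time_bins=128)
        spec = shifted_experiment_spec(
            shift=0.2, n_replicates=8, image_shape=(16, 16),
            photons_per_pixel=10_000.0, acquisition=acq, seed=21,
        )
        cfg = RunConfig(acquisition=acq)
        score = score_timepoint(*simulate_experiment(spec).arms("72h"), cfg)
        assert score.pct_dr > 50.0

    def test_insufficient_replicates_rejected(self, config):
        acq = AcquisitionConfig(n_time_bins=64)
        spec = shifted_experiment_spec(
            shift=0.0, n_replicates=2, image_shape=(4, 4),
            photons_per_pixel=500.0, acquisition=acq,
        )
        controls, treated = simulate_experiment(spec).arms("72h")
        with pytest.raises(InsufficientReplicatesError):
            score_timepoint(controls[:1], treated, RunConfig(acquisition=acq))
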