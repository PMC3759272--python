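"""Ablation experiments and significance testing."""

import numpy as np
import pytest

import eegaffect as ea
from eegaffect.evaluation import holm_correction, paired_test


class TestPairedTest:
    def test_identical_vectors_give_p_one(self):
        assert paired_test([0.7, 0.8, 0.6], [0.7, 0.8, 0.6]) == 1.0

    def test_consistent_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = 0.7 + rng.normal(0, 0.01, size=10)
        b = a - 0.2
        assert paired_test(a, b) < 0.05

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 0.9, size=8)
        b = rng.uniform(0.5, 0.9, size=8)
        assert paired_test(a, b) == pytest.approx(paired_test(b, a))

    def test_matches_closed_form_t_distribution(self):
        # independent oracle: p from the t CDF computed directly
        from scipy import stats

        a = np.array([0.71, 0.69, 0.74, 0.66, 0.72])
        b = np.array([0.65, 0.66, 0.70, 0.61, 0.64])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert paired_test(a, b) == pytest.approx(p_oracle)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_test([0.5], [0.6])
        with pytest.raises(ValueError):
            paired_test([0.5, 0.6], [0.6])

    def test_constant_nonzero_difference_is_reported_certain(self):
        assert paired_test([0.8, 0.8], [0.6, 0.6]) == 0.0


def test_holm_correction_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_correction(p)
    assert all(0 <= v <= 1 for v in adj)
    assert all(a >= o for a, o in zip(adj, p))


@pytest.fixture(scope="module")
def injected_cohort():
    """3 subjects, strong happy-class effect at T7/T8 in beta+gamma."""
    spec = ea.strong_effect_spec(
        seed=21, n_subjects=3, n_trials_per_subject=3,
        stimulus_duration=20.0, rest_duration=5.0,
        bands=("beta", "gamma"),
    )
    return ea.generate_cohort(spec)


@pytest.fixture(scope="module")
def injected_features(injected_cohort):
    return ea.cohort_features(injected_cohort)


class TestChannelPairAblation:
    def test_seven_conditions_ranked_with_effect_pair_first(
        self, injected_features, small_grid
    ):
        report = ea.channel_pair_ablation(injected_features, cfg=small_grid)
        assert len(report.conditions) == 7
        assert report.ranking()[0] == "T7-T8"
        # report is sorted by decreasing mean accuracy
        means = [c.mean_accuracy for c in report.conditions]
        assert means == sorted(means, reverse=True)

    def test_unknown_channel_raises(self, injected_features, small_grid):
        with pytest.raises(KeyError):
            ea.channel_pair_ablation(injected_features, pairs=[("T7", "XX")], cfg=small_grid)


class TestBandAblation:
    def test_effect_bands_rank_highest(self, injected_features, small_grid):
        report = ea.band_ablation(injected_features, cfg=small_grid)
        assert len(report.conditions) == 5
        assert set(report.ranking()[:2]) == {"beta", "gamma"}

    def test_unknown_band_raises(self, injected_features, small_grid):
        with pytest.raises(KeyError):
            ea.band_ablation(injected_features, bands=["sigma"], cfg=small_grid)

    def test_null_cohort_all_bands_at_chance(self, small_grid):
        spec = ea.null_spec(
            seed=22, n_subjects=2, n_trials_per_subject=3,
            stimulus_duration=20.0, rest_duration=5.0,
        )
        fm = ea.cohort_features(ea.generate_cohort(spec))
        cfg = ea.SVMConfig(c_grid=(1.0,), gamma_grid=(2.0 ** -5,))
        report = ea.band_ablation(fm, cfg=cfg)
        n = fm.n_rows / 2  # rows per subject
        se = 0.5 / np.sqrt(n)
        for cond in report.conditions:
            assert abs(cond.mean_accuracy - 0.5) <= 3 * se


class TestDurationAblation:
    def test_three_conditions_with_pairwise_tests(self, injected_cohort, small_grid):
        report = ea.duration_ablation(injected_cohort, cfg=small_grid)
        assert [c.name for c in report.conditions] == [
            "first_half", "second_half", "full",
        ]
        assert len(report.comparisons) == 3
        for _, _, p, name in report.comparisons:
            assert 0.0 <= p <= 1.0 and name == "paired t-test"

    def test_half_conditions_use_half_the_windows(self, protocol_trial, small_grid):
        first = ea.epoch(protocol_trial, 1.0, portion="first_half")
        assert len(first) == 60  # 30 happy + 30 unhappy per trial


class TestModelComparison:
    def test_homogeneous_cohort_schemes_agree(self, small_grid):
        spec = ea.strong_effect_spec(
            seed=23, n_subjects=4, n_trials_per_subject=3,
            stimulus_duration=20.0, rest_duration=5.0,
        )
        fm = ea.cohort_features(ea.generate_cohort(spec))
        report = ea.model_comparison(fm, small_grid)
        loto = report.condition("subject_dependent_LOTO").mean_accuracy
        loso = report.condition("subject_independent_LOSO").mean_accuracy
        assert abs(loto - loso) <= 0.05

    def test_heterogeneous_cohort_loso_below_loto(self, small_grid):
        pairs = [("AF3", "AF4"), ("F3", "F4"), ("P7", "P8"), ("T7", "T8")]
        gains = {
            s: {"happy": {ch: {"gamma": 3.0} for ch in pairs[s]}} for s in range(4)
        }
        spec = ea.CohortSpec(
            n_subjects=4, n_trials_per_subject=3,
            stimulus_duration=20.0, rest_duration=5.0,
            subject_band_gains=gains, seed=24,
        )
        fm = ea.cohort_features(ea.generate_cohort(spec))
        report = ea.model_comparison(fm, small_grid)
        loto = report.condition("subject_dependent_LOTO").mean_accuracy
        loso = report.condition("subject_independent_LOSO").mean_accuracy
        assert loso < loto

    def test_excluding_attenuated_subjects_raises_both_means(self, small_grid):
        spec = ea.strong_effect_spec(
            seed=25, n_subjects=5, n_trials_per_subject=3,
            stimulus_duration=20.0, rest_duration=5.0,
            attenuation_factors={1: 0.1, 3: 0.1},
        )
        fm = ea.cohort_features(ea.generate_cohort(spec))
        report = ea.model_comparison(fm, small_grid, exclude=[1, 3])
        loto = report.condition("subject_dependent_LOTO").mean_accuracy
        loso = report.condition("subject_independent_LOSO").mean_accuracy
        assert report.extras["loto_mean_excluding"] >= loto
        assert report.extras["loso_mean_excluding"] >= loso

    def test_cannot_exclude_every_subject(self, injected_features, small_grid):
        with pytest.raises(ValueError):
            ea.model_comparison(injected_features, small_grid, exclude=[0, 1, 2])


def test_report_round_trip_frames(injected_features, small_grid):
    report = ea.band_ablation(injected_features, bands=["gamma"], cfg=small_grid)
    df = report.to_frame()
    # means recomputable from per-subject columns
    subj_cols = [c for c in df.columns if c.startswith("subject_")]
    np.testing.assert_allclose(
        df[subj_cols].mean(axis=1), df["mean_accuracy"], rtol=1e-12
    )
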