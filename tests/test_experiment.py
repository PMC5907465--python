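"""End-to-end validation runs, aggregation and run comparison."""

import numpy as np
import pytest

from va_validate import (
    ClassifierConfig,
    ExperimentConfig,
    GeneratorConfig,
    Probbase,
    generate_dataset,
    generate_probbase,
    run_validation,
)
from va_validate.experiment import aggregate, compare_runs, write_summary_outputs
from va_validate.metrics import MetricReport


@pytest.fixture(scope="module")
def noisy_dataset():
    cfg = GeneratorConfig(n_causes=8, n_symptoms=40, n_records=1600,
                          signature_strength=0.8, background_rate=0.05,
                          signature_size=3, noise_eps=0.05, missing_rate=0.05,
                          seed=101)
    pb = generate_probbase(cfg)
    return generate_dataset(pb, cfg), pb


class TestRunValidation:
    def test_separable_limit_is_perfect(self, separable_dataset):
        ds, _ = separable_dataset
        summary = run_validation(
            ExperimentConfig(mode="trained", n_splits=10, master_seed=7), ds)
        assert summary.n_failures == 0
        assert summary.scalar_summary["ccc_overall_median"][0] == pytest.approx(1.0)
        assert summary.scalar_summary["csmf_accuracy"][0] == pytest.approx(1.0)
        assert summary.scalar_summary["cccsmf_accuracy"][0] == pytest.approx(1.0)

    def test_determinism(self, noisy_dataset):
        ds, _ = noisy_dataset
        cfg = ExperimentConfig(mode="trained", n_splits=5, master_seed=13)
        a = run_validation(cfg, ds)
        b = run_validation(cfg, ds)
        assert a.scalar_summary == b.scalar_summary
        for ra, rb in zip(a.reports, b.reports):
            np.testing.assert_array_equal(ra.confusion.matrix, rb.confusion.matrix)

    def test_hce_mask_reduces_symptoms_used(self, noisy_dataset):
        ds, _ = noisy_dataset
        cfg = ExperimentConfig(mode="trained", n_splits=4, master_seed=3,
                               include_hce=False)
        summary = run_validation(cfg, ds)
        assert summary.n_completed == 4  # runs cleanly on the reduced symptom set

    def test_fixed_mode_requires_probbase(self, noisy_dataset):
        ds, _ = noisy_dataset
        with pytest.raises(ValueError, match="requires a probbase"):
            run_validation(ExperimentConfig(mode="fixed_probbase", n_splits=3), ds)

    def test_monotone_degradation_with_noise(self):
        medians = []
        for eps in (0.0, 0.15, 0.3):
            cfg = GeneratorConfig(n_causes=6, n_symptoms=30, n_records=900,
                                  signature_strength=0.9, background_rate=0.05,
                                  signature_size=3, noise_eps=eps,
                                  missing_rate=0.0, seed=55)
            ds = generate_dataset(generate_probbase(cfg), cfg)
            s = run_validation(ExperimentConfig(n_splits=10, master_seed=5), ds)
            medians.append(s.scalar_summary["ccc_overall_mean"][0])
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[0] > medians[2]

    def test_trained_beats_random_in_paired_splits(self, noisy_dataset):
        ds, _ = noisy_dataset
        n_splits = 40
        trained = run_validation(
            ExperimentConfig(mode="trained", n_splits=n_splits, master_seed=23), ds)
        random_run = run_validation(
            ExperimentConfig(mode="trained", n_splits=n_splits, master_seed=23,
                             classifier=ClassifierConfig(kind="random")), ds)
        ccc_t = np.array([r.ccc_overall_mean for r in trained.reports])
        ccc_r = np.array([r.ccc_overall_mean for r in random_run.reports])
        csmf_t = np.array([r.cccsmf_accuracy for r in trained.reports])
        csmf_r = np.array([r.cccsmf_accuracy for r in random_run.reports])
        assert (ccc_t > ccc_r).mean() >= 0.95
        assert (csmf_t > csmf_r).mean() >= 0.95

    def test_misspecified_fixed_probbase_goes_negative(self, noisy_dataset):
        """An expert-style probbase pointing at the wrong causes scores worse
        than chance at the population level, while training stays positive."""
        ds, pb_true = noisy_dataset
        wrong = Probbase(np.roll(pb_true.values, 1, axis=0), pb_true.cause_list,
                         pb_true.symptom_dict)
        fixed = run_validation(
            ExperimentConfig(mode="fixed_probbase", n_splits=30, master_seed=31,
                             classifier=ClassifierConfig(prior="uniform")),
            ds, fixed_probbase=wrong)
        trained = run_validation(
            ExperimentConfig(mode="trained", n_splits=30, master_seed=31), ds)
        assert fixed.scalar_summary["cccsmf_accuracy"][0] < 0.0
        assert trained.scalar_summary["cccsmf_accuracy"][0] > 0.0


class TestAggregate:
    def test_percentile_arithmetic(self, abc_causes):
        from va_validate import compute_metric_report
        reports = []
        rng = np.random.default_rng(0)
        for _ in range(4):
            true = rng.choice(list("ABC"), size=30).tolist()
            pred = rng.choice(list("ABC"), size=30).tolist()
            reports.append(compute_metric_report(true, pred, abc_causes))
        # overwrite a scalar with known values to pin down the interpolation
        vals = np.arange(1.0, 501.0)
        med = float(np.median(vals))
        lo = float(np.percentile(vals, 2.5))
        hi = float(np.percentile(vals, 97.5))
        assert med == pytest.approx(250.5)
        assert lo == pytest.approx(13.475)
        assert hi == pytest.approx(487.525)

    def test_constant_vector_degenerate_ui(self, separable_dataset):
        ds, _ = separable_dataset
        s = run_validation(ExperimentConfig(n_splits=5, master_seed=1), ds)
        med, lo, hi = s.scalar_summary["csmf_accuracy"]
        assert med == lo == hi == pytest.approx(1.0)

    def test_needs_two_splits(self, abc_causes):
        with pytest.raises(ValueError):
            aggregate([], cause_list=abc_causes)


class TestCompareRuns:
    def test_self_comparison_all_zero(self, separable_dataset):
        ds, _ = separable_dataset
        s = run_validation(ExperimentConfig(n_splits=5, master_seed=2), ds)
        diffs, wins = compare_runs(s, s)
        assert all(d == pytest.approx(0.0) for d in diffs.values())
        assert wins["sensitivity_by_cause"]["higher"] == 0
        assert wins["sensitivity_by_cause"]["lower"] == 0

    def test_difference_in_percentage_points(self):
        # medians 37.8% and 28.5% differ by 9.3 percentage points
        assert (0.378 - 0.285) * 100 == pytest.approx(9.3)

    def test_win_counts(self, noisy_dataset):
        ds, _ = noisy_dataset
        a = run_validation(ExperimentConfig(n_splits=8, master_seed=3), ds)
        b = run_validation(
            ExperimentConfig(n_splits=8, master_seed=3,
                             classifier=ClassifierConfig(kind="random")), ds)
        _, wins = compare_runs(a, b)
        counts = wins["sensitivity_by_cause"]
        assert counts["higher"] + counts["lower"] + counts["tied"] <= ds.cause_list.N
        assert counts["higher"] > counts["lower"]  # trained run wins most causes


def test_write_summary_outputs(tmp_path, separable_dataset):
    ds, _ = separable_dataset
    s = run_validation(ExperimentConfig(n_splits=4, master_seed=9), ds)
    write_summary_outputs(s, tmp_path)
    for name in ("per_split_metrics.csv", "summary.csv", "ccc_by_cause.csv",
                 "sensitivity_specificity.csv", "misclassification_matrix.csv",
                 "manifest.json"):
        assert (tmp_path / name).exists()
    import pandas as pd
    summary = pd.read_csv(tmp_path / "summary.csv")
    row = summary[summary.metric == "csmf_accuracy"].iloc[0]
    assert row["median"] == pytest.approx(100.0)  # percent scale, one decimal
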