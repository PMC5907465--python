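"""Orchestration of the full validation protocol and median/UI aggregation.

``run_validation`` executes one configuration end-to-end:

* trained mode — for each of ``n_splits`` 75/25 test-train splits: estimate
  the empirical probbase on the train fold, resample the test fold with
  replacement to that split's flat-Dirichlet target cause composition,
  predict a top cause per resampled record, and score;
* fixed-probbase mode — no training: a supplied (e.g. expert-derived)
  probbase predicts for ``n_splits`` test sets, each a with-replacement
  resample of the complete dataset to a flat-Dirichlet composition.

Health-care-experience (HCE) symptoms can be excluded from both data and
probbase to emulate community deaths without prior medical contact.

Per-split metric reports are aggregated to the median and a 95% uncertainty
interval (2.5th/97.5th percentiles, linear interpolation) across splits —
the reporting convention of the validation literature.  Scalar metrics are
kept on the [0, 1] scale internally and rendered as percentages with one
decimal in the exported tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import (
    BayesClassifier,
    ClassifierConfig,
    RandomClassifier,
    estimate_probbase,
    train_csmf_prior,
)
from .datamodel import (
    CauseList,
    Probbase,
    VADataset,
    apply_hce_mask,
)
from .metrics import MetricReport, compute_metric_report
from .splitting import make_splits, draw_dirichlet_csmf, resample_to_csmf, split_seed

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "run_validation",
    "aggregate",
    "compare_runs",
    "write_summary_outputs",
]

MODES = ("trained", "fixed_probbase")


@dataclass
class ExperimentConfig:
    """One validation run: mode, classifier, split design and seed."""

    mode: str = "trained"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_splits: int = 500
    include_hce: bool = True
    master_seed: int = 0
    train_frac: float = 0.75
    dirichlet_alpha: float = 1.0
    smoothing: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected {MODES}")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierConfig(**self.classifier)


@dataclass
class ExperimentSummary:
    """Per-split metric reports plus their median / 95% UI aggregation."""

    config: ExperimentConfig
    reports: list[MetricReport]
    scalar_summary: dict[str, tuple[float, float, float]]  # metric -> (median, lo, hi)
    ccc_by_cause_summary: pd.DataFrame  # cause, median, lo, hi, n_defined
    cause_list: CauseList
    n_failures: int = 0
    failure_log: list[str] = field(default_factory=list)
    flag_log: list[str] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self.reports)


def _resolve_inputs(config, dataset, fixed_probbase):
    if isinstance(dataset, (str, Path)):
        raise TypeError("pass a VADataset; use the CLI for path-based runs")
    if not config.include_hce:
        dataset = apply_hce_mask(dataset, include_hce=False)
        if fixed_probbase is not None:
            fixed_probbase = apply_hce_mask(fixed_probbase, include_hce=False)
    if config.mode == "fixed_probbase" and fixed_probbase is None:
        raise ValueError("fixed_probbase mode requires a probbase")
    return dataset, fixed_probbase


def run_validation(config: ExperimentConfig, dataset: VADataset,
                   fixed_probbase: Probbase | None = None) -> ExperimentSummary:
    """Run the full split / resample / predict / score protocol.

    Split-level failures (e.g. a resample with no feasible cause) are logged
    and skipped; more than 50% failures aborts the run.
    """
    dataset, fixed_probbase = _resolve_inputs(config, dataset, fixed_probbase)
    if config.classifier.kind == "external_plugin":
        raise ValueError(
            "external_plugin predictions are scored offline via the predictions"
            " CSV contract, not inside run_validation"
        )

    gold = dataset.gold_causes
    reports: list[MetricReport] = []
    failures: list[str] = []
    flags: list[str] = []

    if config.mode == "trained":
        plans = make_splits(dataset, n_splits=config.n_splits,
                            train_frac=config.train_frac,
                            master_seed=config.master_seed,
                            alpha=config.dirichlet_alpha)
        for plan in plans:
            try:
                rng = np.random.default_rng(np.random.SeedSequence((plan.seed, 1)))
                train = dataset.subset(plan.train_indices)
                probbase = estimate_probbase(train, smoothing=config.smoothing)
                if probbase.zero_train_causes:
                    flags.append(
                        f"split {plan.index}: zero training records for"
                        f" {list(probbase.zero_train_causes)}"
                    )
                resample = resample_to_csmf(dataset, plan.test_indices,
                                            plan.target_csmf,
                                            size=len(plan.test_indices),
                                            rng=rng, parent_index=plan.index)
                if resample.renormalized:
                    flags.append(f"split {plan.index}: target CSMF renormalised"
                                 " over causes present in the test fold")
                pred = _predict_for_split(config, probbase, train, dataset,
                                          plan.test_indices, rng)
                pos = {idx: k for k, idx in enumerate(plan.test_indices)}
                sel = np.array([pos[i] for i in resample.record_indices])
                report = compute_metric_report(
                    gold[resample.record_indices].tolist(),
                    pred[sel].tolist(),
                    dataset.cause_list,
                )
                reports.append(report)
            except (ValueError, RuntimeError) as exc:
                failures.append(f"split {plan.index}: {exc}")
    else:  # fixed_probbase: no training; resample the complete dataset
        all_indices = np.arange(dataset.n_records)
        pred_full = _predict_fixed(config, fixed_probbase, dataset)
        for i in range(config.n_splits):
            seed = split_seed(config.master_seed, i)
            try:
                rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
                target = draw_dirichlet_csmf(dataset.cause_list.N,
                                             alpha=config.dirichlet_alpha, rng=rng)
                resample = resample_to_csmf(dataset, all_indices, target,
                                            size=dataset.n_records, rng=rng,
                                            parent_index=i)
                report = compute_metric_report(
                    gold[resample.record_indices].tolist(),
                    pred_full[resample.record_indices].tolist(),
                    dataset.cause_list,
                )
                reports.append(report)
            except (ValueError, RuntimeError) as exc:
                failures.append(f"test set {i}: {exc}")

    if len(failures) > config.n_splits / 2:
        raise RuntimeError(
            f"{len(failures)} of {config.n_splits} splits failed; first:"
            f" {failures[0]}"
        )
    scalar_summary, ccc_summary = aggregate(reports, cause_list=dataset.cause_list)
    return ExperimentSummary(
        config=config,
        reports=reports,
        scalar_summary=scalar_summary,
        ccc_by_cause_summary=ccc_summary,
        cause_list=dataset.cause_list,
        n_failures=len(failures),
        failure_log=failures,
        flag_log=flags,
    )


def _predict_for_split(config, probbase, train, dataset, test_indices, rng):
    """Predicted cause labels for the (unique) test-fold records."""
    test = dataset.subset(test_indices)
    if config.classifier.kind == "random":
        clf = RandomClassifier(dataset.cause_list, rng=rng)
    else:
        prior = (train_csmf_prior(train)
                 if config.classifier.prior == "train_csmf" else None)
        clf = BayesClassifier(probbase, config.classifier, prior=prior)
    return clf.predict(test).predicted_causes


def _predict_fixed(config, fixed_probbase, dataset):
    """Predictions over the whole dataset (computed once; probbase is fixed)."""
    if config.classifier.kind == "random":
        clf = RandomClassifier(dataset.cause_list,
                               rng=np.random.default_rng(split_seed(config.master_seed, 0)))
    else:
        # no training data, so a uniform prior regardless of config.prior
        clf = BayesClassifier(fixed_probbase, config.classifier, prior=None)
    return clf.predict(dataset).predicted_causes


def aggregate(reports: list[MetricReport], cause_list: CauseList,
              percentiles: tuple[float, float] = (2.5, 97.5)):
    """Median and UI per scalar metric and per-cause CCC across splits.

    Non-finite values (e.g. CCC for a cause absent from a split's test set)
    are excluded, with the number of contributing splits recorded.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 completed splits to aggregate")
    lo_p, hi_p = percentiles
    scalar_summary: dict[str, tuple[float, float, float]] = {}
    for name in MetricReport.SCALAR_METRICS:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            scalar_summary[name] = (float("nan"),) * 3
            continue
        med = float(np.median(vals))
        lo = float(np.percentile(vals, lo_p))
        hi = float(np.percentile(vals, hi_p))
        assert lo <= med <= hi
        scalar_summary[name] = (med, lo, hi)

    ccc_mat = np.vstack([r.ccc_by_cause for r in reports])  # (splits, N)
    rows = []
    for j, cause in enumerate(cause_list.causes):
        col = ccc_mat[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            rows.append((cause, float(np.median(col)),
                         float(np.percentile(col, lo_p)),
                         float(np.percentile(col, hi_p)), int(col.size)))
        else:
            rows.append((cause, float("nan"), float("nan"), float("nan"), 0))
    ccc_summary = pd.DataFrame(rows, columns=["cause", "median", "ui_lo", "ui_hi",
                                              "n_defined"])
    return scalar_summary, ccc_summary


def compare_runs(summary_a: ExperimentSummary, summary_b: ExperimentSummary):
    """Difference-in-medians table (percentage points) plus per-cause wins.

    Returns (scalar_diffs, wins): ``scalar_diffs`` maps each metric to
    (median_a - median_b) * 100; ``wins`` counts causes where run A's median
    per-split sensitivity/specificity is higher, lower, or tied vs run B.
    """
    if summary_a.cause_list.causes != summary_b.cause_list.causes:
        raise ValueError("runs use different cause lists")
    if set(summary_a.scalar_summary) != set(summary_b.scalar_summary):
        raise ValueError("runs report different metric sets")
    scalar_diffs = {
        name: (summary_a.scalar_summary[name][0] - summary_b.scalar_summary[name][0]) * 100.0
        for name in summary_a.scalar_summary
    }
    wins: dict[str, dict[str, int]] = {}
    for attr in ("sensitivity_by_cause", "specificity_by_cause"):
        med_a = _per_cause_median(summary_a, attr)
        med_b = _per_cause_median(summary_b, attr)
        higher = lower = tied = 0
        for a, b in zip(med_a, med_b):
            if np.isnan(a) or np.isnan(b):
                continue
            if a > b:
                higher += 1
            elif a < b:
                lower += 1
            else:
                tied += 1
        wins[attr] = {"higher": higher, "lower": lower, "tied": tied}
    return scalar_diffs, wins


def _per_cause_median(summary: ExperimentSummary, attr: str) -> np.ndarray:
    mat = np.vstack([getattr(r, attr) for r in summary.reports])
    with np.errstate(all="ignore"):
        return np.nanmedian(mat, axis=0)


# ---------------------------------------------------------------------------
# Exported tables (percent scale, one decimal) and run manifest
# ---------------------------------------------------------------------------

def _pct(x: float) -> float:
    return round(float(x) * 100.0, 1)


def write_summary_outputs(summary: ExperimentSummary, out_dir) -> None:
    """Write per-split metrics, summary, per-cause CCC, sensitivity/
    specificity, the pooled misclassification matrix, and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_split = pd.DataFrame([r.scalars() for r in summary.reports])
    per_split.insert(0, "split", range(len(summary.reports)))
    per_split.to_csv(out / "per_split_metrics.csv", index=False)

    rows = [
        {"metric": name, "median": _pct(med), "ui_lo": _pct(lo), "ui_hi": _pct(hi)}
        for name, (med, lo, hi) in summary.scalar_summary.items()
    ]
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)

    ccc = summary.ccc_by_cause_summary.copy()
    for col in ("median", "ui_lo", "ui_hi"):
        ccc[col] = (ccc[col] * 100.0).round(1)
    ccc.to_csv(out / "ccc_by_cause.csv", index=False)

    sens = _per_cause_median(summary, "sensitivity_by_cause")
    spec = _per_cause_median(summary, "specificity_by_cause")
    pd.DataFrame({
        "cause": list(summary.cause_list.causes),
        "sensitivity_median": np.round(sens * 100.0, 1),
        "specificity_median": np.round(spec * 100.0, 1),
    }).to_csv(out / "sensitivity_specificity.csv", index=False)

    pooled = np.sum([r.confusion.matrix for r in summary.reports], axis=0)
    pd.DataFrame(pooled, index=list(summary.cause_list.causes),
                 columns=list(summary.cause_list.causes)).to_csv(
        out / "misclassification_matrix.csv")

    manifest = {
        "mode": summary.config.mode,
        "classifier": asdict(summary.config.classifier),
        "n_splits": summary.config.n_splits,
        "n_completed": summary.n_completed,
        "n_failures": summary.n_failures,
        "include_hce": summary.config.include_hce,
        "master_seed": summary.config.master_seed,
        "train_frac": summary.config.train_frac,
        "dirichlet_alpha": summary.config.dirichlet_alpha,
        "flags": summary.flag_log[:100],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def plot_accuracy_scatter(summaries: dict[str, ExperimentSummary], path) -> None:
    """Scatter of median overall CCC vs median CCCSMF per configuration."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, summary in summaries.items():
        x = summary.scalar_summary["ccc_overall_mean"][0] * 100
        y = summary.scalar_summary["cccsmf_accuracy"][0] * 100
        ax.scatter([x], [y], label=label)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("median chance-corrected concordance (%)")
    ax.set_ylabel("median CCCSMF accuracy (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
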