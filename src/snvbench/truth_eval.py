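"""Scoring against a known truth set, and truth-vs-validation comparison.

In simulation mode the true somatic variants of each sample are known, so
pipelines (and combinations) can be scored by exact set algebra against
truth.  Comparing these truth-based metrics with the cross-sample
validation-based ones quantifies how well the validation statistic stands
in for ground truth — and exposes its failure mode when false calls recur
across samples.
"""

from __future__ import annotations

from typing import Iterable, Set

import pandas as pd

from .metrics import MetricsRecord, score_counts
from .vcf_io import CallSet, VariantKey

#: Truth-based metrics share the shape of validation-based ones.
TruthMetrics = MetricsRecord


def score_vs_truth(cs: CallSet, truth: Set[VariantKey]) -> TruthMetrics:
    """Score one call set against the sample's true variant set.

    ``truth`` should contain the variants genuinely present in the sample
    (variants of clones active in it) — a pipeline cannot find a variant
    absent from the sample's cells.  tp = calls & truth, fp = calls - truth,
    fn = truth - calls; with empty truth, recall is undefined (NaN).
    """
    calls = cs.keys()
    tp = len(calls & truth)
    fp = len(calls - truth)
    fn = len(truth - calls)
    return score_counts(cs.pipeline_id, cs.sample_id, tp, fp, fn)


def truth_metrics_frame(
    callsets: Iterable[CallSet], truth_by_sample: dict[str, Set[VariantKey]]
) -> pd.DataFrame:
    """Tidy truth-based metrics for many call sets (one row per unit x sample)."""
    rows = []
    for cs in callsets:
        if cs.sample_id not in truth_by_sample:
            raise KeyError(f"no truth set for sample {cs.sample_id!r}")
        r = score_vs_truth(cs, truth_by_sample[cs.sample_id])
        rows.append((r.unit_id, r.sample_id, r.tp, r.fp, r.fn, r.precision, r.recall, r.f1))
    return pd.DataFrame(
        rows,
        columns=["unit_id", "sample_id", "tp", "fp", "fn", "precision", "recall", "f1"],
    )


def compare_validation_to_truth(
    validation_metrics: pd.DataFrame, truth_metrics: pd.DataFrame
) -> pd.DataFrame:
    """Per (unit, sample) deltas: validation-based minus truth-based.

    Both frames need (unit_id, sample_id, precision, recall, f1) rows for
    the same runs; a mismatch in keys raises with the missing pairs listed.
    Positive ``delta_precision`` means validation *overestimates*
    precision (e.g. recurrent artifacts passing validation).
    """
    keys = ["unit_id", "sample_id"]
    left = set(map(tuple, validation_metrics[keys].itertuples(index=False)))
    right = set(map(tuple, truth_metrics[keys].itertuples(index=False)))
    if left != right:
        missing = sorted(left ^ right)[:10]
        raise ValueError(
            f"validation and truth metrics cover different runs; "
            f"first mismatched (unit, sample) pairs: {missing}"
        )
    merged = validation_metrics.merge(
        truth_metrics, on=keys, suffixes=("_validation", "_truth")
    )
    for col in ("precision", "recall", "f1"):
        merged[f"delta_{col}"] = merged[f"{col}_validation"] - merged[f"{col}_truth"]
    return merged


def summarize_deltas(comparison: pd.DataFrame) -> pd.DataFrame:
    """Mean deltas per unit (pipeline or combination) across samples."""
    cols = ["delta_precision", "delta_recall", "delta_f1",
            "precision_validation", "precision_truth",
            "recall_validation", "recall_truth"]
    return comparison.groupby("unit_id", sort=True)[cols].mean().reset_index()


def pooled_precision(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-unit precision from pooled counts (sum tp / sum (tp + fp))."""
    g = metrics.groupby("unit_id", sort=True)[["tp", "fp", "fn"]].sum().reset_index()
    g["precision"] = g["tp"] / (g["tp"] + g["fp"])
    g["recall"] = g["tp"] / (g["tp"] + g["fn"])
    return g
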