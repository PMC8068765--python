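"""Precision / recall / F1 per (pipeline, sample), and mapper/caller summaries.

precision = tp / (tp + fp), recall = tp / (tp + fn), F1 their harmonic
mean, all computed from integer counts.  Undefined ratios (zero
denominator) are NaN, never coerced to 0, and aggregation means skip them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .validation import Classification
from .vcf_io import CallSet, split_pipeline_id


@dataclass(frozen=True)
class MetricsRecord:
    """Counts and derived scores for one evaluation unit on one sample.

    ``unit_id`` is a pipeline id or a combination id.  Undefined metrics
    are ``nan``.
    """

    unit_id: str
    sample_id: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def score_counts(unit_id: str, sample_id: str, tp: int, fp: int, fn: int) -> MetricsRecord:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    # F1 from counts directly (harmonic mean), avoiding double rounding.
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else math.nan
    return MetricsRecord(unit_id, sample_id, tp, fp, fn, precision, recall, f1)


def score(c: Classification) -> MetricsRecord:
    """Score one classification."""
    return score_counts(c.pipeline_id, c.sample_id, len(c.tp), len(c.fp), len(c.fn))


def metrics_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Tidy table with one row per (unit, sample)."""
    return pd.DataFrame(
        [
            (r.unit_id, r.sample_id, r.tp, r.fp, r.fn, r.precision, r.recall, r.f1)
            for r in records
        ],
        columns=["unit_id", "sample_id", "tp", "fp", "fn", "precision", "recall", "f1"],
    )


def count_matrix(callsets: Iterable[CallSet]) -> pd.DataFrame:
    """Samples x pipelines matrix of filtered call counts.

    Missing (pipeline, sample) pairs are NaN, not 0, so absent runs are
    distinguishable from empty call sets.
    """
    rows = [
        {"sample_id": cs.sample_id, "pipeline_id": cs.pipeline_id, "n_calls": len(cs)}
        for cs in callsets
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "pipeline_id", "n_calls"])
    if df.empty:
        return pd.DataFrame()
    return df.pivot(index="sample_id", columns="pipeline_id", values="n_calls")


def _aggregate(metrics: pd.DataFrame, counts: pd.DataFrame | None, group: str) -> pd.DataFrame:
    df = metrics.copy()
    parts = df["unit_id"].map(lambda u: split_pipeline_id(u))
    df["mapper"] = parts.map(lambda t: t[0])
    df["caller"] = parts.map(lambda t: t[1])
    if counts is not None:
        df = df.merge(
            counts.rename(columns={"pipeline_id": "unit_id"}),
            on=["unit_id", "sample_id"],
            how="left",
        )
    value_cols = [c for c in ("n_calls", "precision", "recall", "f1") if c in df.columns]
    grouped = df.groupby([group, "sample_id"], sort=True)
    out = grouped[value_cols].mean().reset_index()
    out["n_pipelines"] = grouped.size().values
    return out


def aggregate_by_mapper(metrics: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (mapper, sample): mean over the callers sharing the mapper.

    ``counts`` is an optional tidy frame (pipeline_id, sample_id, n_calls)
    whose means land in an ``n_calls`` column.  Means skip NaN; the
    ``n_pipelines`` column exposes how many pipelines contributed so that a
    missing caller is visible.
    """
    return _aggregate(metrics, counts, "mapper")


def aggregate_by_caller(metrics: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (caller, sample): mean over the mappers sharing the caller."""
    return _aggregate(metrics, counts, "caller")


def counts_frame(callsets: Iterable[CallSet]) -> pd.DataFrame:
    """Tidy (pipeline_id, sample_id, n_calls) companion to the metrics table."""
    return pd.DataFrame(
        [
            {"pipeline_id": cs.pipeline_id, "sample_id": cs.sample_id, "n_calls": len(cs)}
            for cs in callsets
        ],
        columns=["pipeline_id", "sample_id", "n_calls"],
    )
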