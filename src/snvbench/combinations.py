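"""Union combinations of pipelines and best-F1 selection.

The union of several pipelines' call sets is scored exactly like a single
pipeline against the *same* validated set (computed once from individual
pipelines; unions never feed back into validation).  For n pipelines all
2^n - 1 non-empty subsets are scored per sample; counting is done on
per-variant detection bitmasks with a sum-over-subsets transform, so the
full 4095-combination sweep over a 50-sample study takes seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .metrics import score_counts
from .validation import FnScope, ValidatedSet, ValidationIndex, validated_in_sample
from .vcf_io import CallRecord, CallSet


@dataclass(frozen=True)
class Combination:
    """A non-empty set of pipelines, identified order-independently."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a combination needs at least one member")

    @property
    def id(self) -> str:
        return "+".join(sorted(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


def enumerate_combinations(
    pipelines: Iterable[str], max_size: int | None = None
) -> Iterator[Combination]:
    """Yield every non-empty pipeline subset up to ``max_size``, once each.

    Deterministic order: by size, then lexicographically by canonical id.
    ``max_size=None`` means all sizes (2^n - 1 subsets for n pipelines).
    """
    pipelines = sorted(set(pipelines))
    if not pipelines:
        raise ValueError("need at least one pipeline")
    if max_size is None:
        max_size = len(pipelines)
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    max_size = min(max_size, len(pipelines))
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(pipelines, k):
            yield Combination(frozenset(combo))


def union_callset(
    callsets: Mapping[str, CallSet], members: Iterable[str]
) -> CallSet:
    """Set-union of the member pipelines' call sets for one sample.

    Per-variant metadata (depth, alt reads, VAF) is taken from the member
    with the highest depth; it is informational only and does not affect
    scoring.
    """
    members = sorted(set(members))
    missing = [m for m in members if m not in callsets]
    if missing:
        raise ValueError(f"no call set for pipeline(s) {missing}")
    first = callsets[members[0]]
    combo = Combination(frozenset(members))
    best: dict = {}
    for m in members:
        cs = callsets[m]
        if cs.sample_id != first.sample_id:
            raise ValueError(
                f"call sets span different samples: {cs.sample_id} vs {first.sample_id}"
            )
        for rec in cs:
            cur = best.get(rec.key)
            if cur is None or rec.depth > cur.depth:
                best[rec.key] = rec
    records = [
        CallRecord(r.key, r.depth, r.alt_reads, r.vaf, r.filter_status)
        for r in best.values()
    ]
    return CallSet(combo.id, first.sample_id, first.sample_type, records)


def _sum_over_subsets(counts: np.ndarray, n_bits: int) -> np.ndarray:
    """f[m] = sum of counts[u] over u subset-of m (in-place SOS transform)."""
    f = counts.astype(np.int64).copy()
    size = 1 << n_bits
    for b in range(n_bits):
        bit = 1 << b
        idx = np.arange(size)
        has = (idx & bit).astype(bool)
        f[has] += f[idx[has] ^ bit]
    return f


def score_combinations(
    callsets: Mapping[str, CallSet],
    validated: ValidatedSet,
    index: ValidationIndex,
    fn_scope: FnScope = "per_sample",
    max_size: int | None = None,
    pipelines: list[str] | None = None,
) -> pd.DataFrame:
    """Score every pipeline combination for one sample.

    ``callsets`` maps pipeline id -> that pipeline's filtered call set for
    one sample.  Returns a frame with one row per combination
    (combination_id, size, tp, fp, fn, precision, recall, f1) in
    enumeration order.  TP/FP/FN follow the same definitions as for single
    pipelines; the validated set is held fixed.
    """
    if pipelines is None:
        pipelines = sorted(callsets)
    n = len(pipelines)
    if n < 1:
        raise ValueError("need at least one pipeline")
    if n > 20:
        raise ValueError(f"refusing to enumerate 2^{n} combinations")
    sample_ids = {cs.sample_id for cs in callsets.values()}
    if len(sample_ids) != 1:
        raise ValueError(f"call sets span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    # per-variant detection bitmask over the sample's call universe
    universe: dict = {}
    for i, pid in enumerate(pipelines):
        if pid not in callsets:
            raise ValueError(f"no call set for pipeline {pid!r} in sample {sample_id}")
        for key in callsets[pid].keys():
            universe[key] = universe.get(key, 0) | (1 << i)
    masks = np.fromiter(universe.values(), dtype=np.int64, count=len(universe))
    is_val = np.fromiter(
        (k in validated for k in universe), dtype=bool, count=len(universe)
    )

    size = 1 << n
    counts_all = np.bincount(masks, minlength=size)
    counts_tp = np.bincount(masks[is_val], minlength=size)
    sos_all = _sum_over_subsets(counts_all, n)
    sos_tp = _sum_over_subsets(counts_tp, n)
    total_all, total_tp = int(counts_all.sum()), int(counts_tp.sum())

    if fn_scope == "per_sample":
        # FN pool = validated variants some indexed pipeline saw in this sample
        n_val_scope = len(validated_in_sample(validated, index, sample_id))
    elif fn_scope == "global":
        n_val_scope = len(validated)
    else:
        raise ValueError(f"unknown fn_scope {fn_scope!r}")

    rows = []
    full = size - 1
    for combo in enumerate_combinations(pipelines, max_size):
        m = 0
        for pid in combo.members:
            m |= 1 << pipelines.index(pid)
        # calls(m) = variants whose mask intersects m = total - (masks within ~m)
        ncalls = total_all - int(sos_all[full & ~m])
        tp = total_tp - int(sos_tp[full & ~m])
        fp = ncalls - tp
        fn = n_val_scope - tp
        rec = score_counts(combo.id, sample_id, tp, fp, fn)
        rows.append((combo.id, combo.size, tp, fp, fn, rec.precision, rec.recall, rec.f1))
    return pd.DataFrame(
        rows,
        columns=["combination_id", "size", "tp", "fp", "fn", "precision", "recall", "f1"],
    )


def best_per_sample(results: pd.DataFrame, by_size: bool = False) -> pd.DataFrame:
    """Best-F1 combination(s) for one sample's combination results.

    Returns the overall argmax row; with ``by_size`` also the best
    combination of each exact size.  Ties break toward the smaller
    combination, then the lexicographically smaller id.  When every F1 is
    missing an empty frame is returned (caller should warn and skip).
    """
    df = results.dropna(subset=["f1"])
    if df.empty:
        return df.assign(scope=pd.Series(dtype=str))
    ranked = df.sort_values(
        ["f1", "size", "combination_id"], ascending=[False, True, True], kind="mergesort"
    )
    rows = [ranked.iloc[0].to_dict() | {"scope": "overall"}]
    if by_size:
        for k, grp in ranked.groupby("size", sort=True):
            rows.append(grp.iloc[0].to_dict() | {"scope": f"size_{int(k)}"})
    return pd.DataFrame(rows)


def tally_winners(
    winners: pd.DataFrame, sample_types: Mapping[str, str], sizes: Iterable[int] = (1, 2, 3)
) -> pd.DataFrame:
    """Occurrence counts of per-sample winning combinations by sample type.

    ``winners`` needs columns sample_id, combination_id, size, scope (from
    :func:`best_per_sample` with ``by_size=True``); ``sample_types`` maps
    sample id -> type.  For each requested size, counts how many samples
    each combination won, split by sample type, sorted by total descending
    (ties by size then id).
    """
    sizes = sorted(set(int(s) for s in sizes))
    df = winners[winners["scope"].isin([f"size_{k}" for k in sizes])].copy()
    if df.empty:
        return pd.DataFrame(columns=["combination_id", "size", "total"])
    df["sample_type"] = df["sample_id"].map(dict(sample_types))
    tab = (
        df.groupby(["combination_id", "size", "sample_type"], sort=False)
        .size()
        .unstack("sample_type", fill_value=0)
    )
    tab["total"] = tab.sum(axis=1)
    tab = tab.reset_index().sort_values(
        ["total", "size", "combination_id"], ascending=[False, True, True], kind="mergesort"
    )
    return tab.reset_index(drop=True)


def f1_by_size(results_by_sample: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format best-F1-per-size table across samples.

    ``results_by_sample`` maps sample id -> :func:`score_combinations`
    output.  For each sample and combination size the best F1 is reported
    (plus which combination achieved it), suitable for boxplots of F1
    against combination size.  No unimodality is assumed or asserted.
    """
    rows = []
    for sid, res in results_by_sample.items():
        best = best_per_sample(res, by_size=True)
        for _, r in best[best["scope"].str.startswith("size_")].iterrows():
            rows.append(
                {
                    "sample_id": sid,
                    "size": int(r["size"]),
                    "combination_id": r["combination_id"],
                    "f1": r["f1"],
                    "precision": r["precision"],
                    "recall": r["recall"],
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "size", "combination_id", "f1", "precision", "recall"]
    )
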