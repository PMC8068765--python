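"""Cross-sample validation of somatic SNV calls.

Without a ground truth, a variant detected in at least two independent
samples of the same tumor is declared *validated*: an identical false
discovery recurring across samples is unlikely.  Each pipeline's calls for
a sample are then classified against the validated set: a true positive is
the detection of a validated variant, a false positive the detection of a
non-validated one, and a false negative the lack of detection of a
validated variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .vcf_io import CallSet, VariantKey

FnScope = Literal["per_sample", "global"]


@dataclass
class ValidationIndex:
    """For each variant, which (pipeline, sample) pairs detected it."""

    detections: dict[VariantKey, set[tuple[str, str]]] = field(default_factory=dict)
    #: (pipeline_id, sample_id) pairs the index was built from.
    units: set[tuple[str, str]] = field(default_factory=set)
    # lazy projection caches, built on first query (after the index is complete)
    _samples_of: dict[VariantKey, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )
    _pipelines_of: dict[VariantKey, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def samples_of(self, v: VariantKey) -> frozenset[str]:
        if self._samples_of is None:
            self._samples_of = {
                k: frozenset(s for _, s in dets) for k, dets in self.detections.items()
            }
        return self._samples_of.get(v, frozenset())

    def pipelines_of(self, v: VariantKey) -> frozenset[str]:
        if self._pipelines_of is None:
            self._pipelines_of = {
                k: frozenset(p for p, _ in dets) for k, dets in self.detections.items()
            }
        return self._pipelines_of.get(v, frozenset())

    def __len__(self) -> int:
        return len(self.detections)

    def __contains__(self, v: VariantKey) -> bool:
        return v in self.detections


@dataclass(frozen=True)
class ValidatedSet:
    validated: frozenset[VariantKey]
    min_samples: int
    min_pipelines: int

    def __contains__(self, v: VariantKey) -> bool:
        return v in self.validated

    def __len__(self) -> int:
        return len(self.validated)


@dataclass
class Classification:
    """TP/FP/FN variant sets for one (pipeline, sample)."""

    pipeline_id: str
    sample_id: str
    tp: frozenset[VariantKey]
    fp: frozenset[VariantKey]
    fn: frozenset[VariantKey]

    def __post_init__(self) -> None:
        if self.tp & self.fp or self.fn & (self.tp | self.fp):
            raise ValueError("tp, fp, fn must be pairwise disjoint")


def build_index(callsets: Iterable[CallSet]) -> ValidationIndex:
    """Index every variant by the (pipeline, sample) pairs that detected it."""
    idx = ValidationIndex()
    for cs in callsets:
        unit = (cs.pipeline_id, cs.sample_id)
        if unit in idx.units:
            raise ValueError(f"duplicate call set for (pipeline, sample) {unit}")
        idx.units.add(unit)
        for key in cs.keys():
            idx.detections.setdefault(key, set()).add(unit)
    return idx


def validate(
    index: ValidationIndex, min_samples: int = 2, min_pipelines: int = 1
) -> ValidatedSet:
    """Compute the validated-variant set.

    A variant is validated when detected in >= ``min_samples`` distinct
    samples and by >= ``min_pipelines`` distinct pipelines (pooled across
    pipelines by default, so detections by different pipelines in different
    samples corroborate each other).
    """
    if min_samples < 1 or min_pipelines < 1:
        raise ValueError("min_samples and min_pipelines must be >= 1")
    validated = frozenset(
        v
        for v, dets in index.detections.items()
        if len({s for _, s in dets}) >= min_samples
        and len({p for p, _ in dets}) >= min_pipelines
    )
    return ValidatedSet(validated, min_samples, min_pipelines)


def validated_in_sample(
    validated: ValidatedSet, index: ValidationIndex, sample_id: str
) -> set[VariantKey]:
    """Validated variants that some pipeline detected in ``sample_id``."""
    return {
        v for v in validated.validated if sample_id in index.samples_of(v)
    }


def classify(
    cs: CallSet,
    validated: ValidatedSet,
    index: ValidationIndex,
    fn_scope: FnScope = "per_sample",
) -> Classification:
    """Classify one pipeline's calls for one sample as TP/FP/FN.

    Under the default ``per_sample`` scope a pipeline is charged a false
    negative only for validated variants that some pipeline detected in the
    same sample; under ``global`` scope, for every validated variant.  The
    per-sample scope reflects that samples genuinely differ in the variants
    they harbor.
    """
    unit = (cs.pipeline_id, cs.sample_id)
    if unit not in index.units:
        raise ValueError(f"call set {unit} was not part of the validation index")
    if fn_scope not in ("per_sample", "global"):
        raise ValueError(f"unknown fn_scope {fn_scope!r}")

    calls = cs.keys()
    tp = frozenset(calls & validated.validated)
    fp = frozenset(calls - validated.validated)
    if fn_scope == "per_sample":
        scope = validated_in_sample(validated, index, cs.sample_id)
    else:
        scope = set(validated.validated)
    fn = frozenset(scope - calls)
    return Classification(cs.pipeline_id, cs.sample_id, tp, fp, fn)
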