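"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use nothing from the package but the plain data
types: they loop over every (variant, pipeline, sample) triple with python
sets, so the fast implementations can be checked against them exactly.
"""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

import snvbench as sb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_callset(pipeline_id, sample_id, keys, sample_type="monoclone", depth=50):
    """CallSet from (contig, pos, ref, alt) tuples with uniform metadata."""
    records = [
        sb.CallRecord(sb.VariantKey(*k), depth=depth, alt_reads=depth // 5, vaf=0.2)
        for k in keys
    ]
    return sb.CallSet(pipeline_id, sample_id, sample_type, records)


# -- brute-force oracles ----------------------------------------------------

def brute_validated(callsets, min_samples=2, min_pipelines=1):
    """Validated set by direct enumeration over all call sets."""
    all_keys = set()
    for cs in callsets:
        all_keys |= cs.keys()
    validated = set()
    for v in all_keys:
        samples = {cs.sample_id for cs in callsets if v in cs}
        pipelines = {cs.pipeline_id for cs in callsets if v in cs}
        if len(samples) >= min_samples and len(pipelines) >= min_pipelines:
            validated.add(v)
    return validated


def brute_classify(cs, callsets, validated, fn_scope="per_sample"):
    """TP/FP/FN by looping over every variant with plain set logic."""
    calls = cs.keys()
    tp = {v for v in calls if v in validated}
    fp = calls - tp
    if fn_scope == "per_sample":
        in_sample = {
            v
            for v in validated
            if any(o.sample_id == cs.sample_id and v in o for o in callsets)
        }
    else:
        in_sample = set(validated)
    fn = in_sample - calls
    return tp, fp, fn


def brute_combination_scores(sample_callsets, validated, in_sample_validated):
    """Score every non-empty pipeline subset by explicit union set algebra."""
    pipelines = sorted(sample_callsets)
    out = {}
    for k in range(1, len(pipelines) + 1):
        for members in itertools.combinations(pipelines, k):
            union = set()
            for m in members:
                union |= sample_callsets[m].keys()
            tp = len(union & validated)
            fp = len(union - validated)
            fn = len(in_sample_validated - union)
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
            out["+".join(sorted(members))] = (tp, fp, fn, f1)
    return out


# -- fixtures ---------------------------------------------------------------

VARS = [
    ("chr1", 100, "A", "T"),
    ("chr1", 200, "C", "G"),
    ("chr2", 50, "G", "A"),
    ("chr2", 75, "T", "C"),
    ("chr3", 10, "A", "C"),
]
a, b, c, d, e = (sb.VariantKey(*v) for v in VARS)


@pytest.fixture
def toy_callsets():
    """2 pipelines x 3 samples, 5 distinct variants, hand-enumerable.

    Variant support (samples containing it): a in S1+S2, b in S1+S2+S3,
    c in S1 only, d in S2+S3, e in S3 only.  Under the default rule
    {a, b, d} are validated.
    """
    return [
        make_callset("Bwa_Mutect2", "S1", [VARS[0], VARS[1], VARS[2]]),
        make_callset("Novoalign_Strelka2", "S1", [VARS[0], VARS[1]]),
        make_callset("Bwa_Mutect2", "S2", [VARS[0], VARS[3]]),
        make_callset("Novoalign_Strelka2", "S2", [VARS[1], VARS[3]]),
        make_callset("Bwa_Mutect2", "S3", [VARS[1]]),
        make_callset("Novoalign_Strelka2", "S3", [VARS[3], VARS[4]]),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down simulated study shared by the slower integration tests."""
    config = sb.StudyConfig(
        n_variants=600,
        seed=11,
        design=sb.SampleDesign(
            counts={
                "parental": 2,
                "invivo_polyclone": 3,
                "invitro_polyclone": 2,
                "monoclone": 4,
                "secondary_monoclone": 1,
            }
        ),
    )
    return sb.simulate_study(config)


@pytest.fixture(scope="session")
def small_study_eval(small_study):
    """Filtered call sets + validation products for the small study."""
    filtered = {k: sb.apply_filters(cs) for k, cs in small_study.callsets.items()}
    index = sb.build_index(filtered.values())
    validated = sb.validate(index)
    return filtered, index, validated
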