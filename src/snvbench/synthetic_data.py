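"""Truth-known synthetic somatic SNV study generator.

Emulates the structure of a multi-region tumor sequencing study at the
*call* level: a pool of truth variants partitioned into clones, ~50 samples
of five heterogeneity types (multi-region parental tumor pieces, in-vivo
and in-vitro polyclones, monoclones, secondary monoclones), and 12
mapper x caller pipelines with distinct behavioral profiles.  Reads are not
simulated; instead each variant's observable allele fraction follows the
heterozygous-diploid relation

    E[VAF] = purity x clone_fraction_in_sample x 0.5,

site depth is Poisson around the target coverage, alt-read support is
binomial, and each pipeline calls a variant with a logistic sensitivity in
VAF plus a Poisson number of false calls, optionally drawn from a shared
artifact pool that recurs across samples (the failure mode of cross-sample
validation).

All randomness flows from one master seed through named substreams, so
outputs are reproducible and adding a pipeline does not perturb others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .vcf_io import (
    CALLERS,
    MAPPERS,
    CallRecord,
    CallSet,
    VariantKey,
    write_manifest,
    write_vcf,
)

# substream tags (stable small ints mixed into SeedSequence entropy)
_STREAMS = {"truth": 1, "artifacts": 2, "sample": 3, "pipeline": 4, "design": 5}


def _rng(seed: int, stream: str, *indices: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, indices)])
    )


def purity_from_mixing(tumor_coverage: float, normal_coverage: float) -> float:
    """Tumor purity produced by pooling tumor reads with normal reads.

    Mixing a tumor read set of coverage t with a normal read set of
    coverage n yields a sample whose tumor read fraction — its purity — is
    t / (t + n): 20x tumor + 80x normal gives 20% purity, 80x + 80x gives
    50%, and an unmixed tumor is 100% pure.
    """
    if tumor_coverage <= 0:
        raise ValueError("tumor_coverage must be > 0")
    if normal_coverage < 0:
        raise ValueError("normal_coverage must be >= 0")
    return tumor_coverage / (tumor_coverage + normal_coverage)


# ---------------------------------------------------------------------------
# exome intervals

Interval = tuple[str, int, int]  # contig, 0-based start, end (BED half-open)


def default_exome(
    n_contigs: int = 10, intervals_per_contig: int = 10, interval_length: int = 10_000
) -> list[Interval]:
    """Toy exome: 10 contigs x 10 intervals x 10 kb = 1 Mb of callable space."""
    exome = []
    for c in range(1, n_contigs + 1):
        for j in range(intervals_per_contig):
            start = j * 100_000
            exome.append((f"chr{c}", start, start + interval_length))
    return exome


def write_bed(exome: Sequence[Interval], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in exome)
    )


def read_bed(path: str | Path) -> list[Interval]:
    exome = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        c, s, e = line.split("\t")[:3]
        exome.append((c, int(s), int(e)))
    return exome


def _offsets_to_keys(
    exome: Sequence[Interval], offsets: np.ndarray, refs: np.ndarray, alts: np.ndarray
) -> list[VariantKey]:
    lengths = np.array([e - s for _, s, e in exome])
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    which = np.searchsorted(bounds, offsets, side="right") - 1
    keys = []
    for off, iv, r, a in zip(offsets, which, refs, alts):
        contig, start, _ = exome[iv]
        pos = start + int(off - bounds[iv]) + 1  # 1-based VCF position
        keys.append(VariantKey(contig, pos, r, a))
    return keys


_B = np.array(list("ACGT"))


def _random_keys(exome: Sequence[Interval], n: int, rng: np.random.Generator) -> list[VariantKey]:
    total = sum(e - s for _, s, e in exome)
    if n > total:
        raise ValueError(f"exome of {total} bp cannot host {n} distinct positions")
    offsets = rng.choice(total, size=n, replace=False)
    refs = _B[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)  # alt != ref by construction
    alts = _B[(np.searchsorted(_B, refs) + alt_shift) % 4]
    return _offsets_to_keys(exome, offsets, refs, alts)


# ---------------------------------------------------------------------------
# truth model and sample design


@dataclass
class TruthModel:
    """Truth variants with clone assignments over a toy exome."""

    variants: list[VariantKey]
    clone_of: np.ndarray  # clone index per variant
    clone_weights: np.ndarray  # Dirichlet weights used for assignment
    exome: list[Interval]
    seed: int

    @property
    def n_clones(self) -> int:
        return len(self.clone_weights)

    def __len__(self) -> int:
        return len(self.variants)


def generate_truth(
    n_variants: int = 4800,
    exome: Sequence[Interval] | None = None,
    n_clones: int = 8,
    seed: int = 0,
) -> TruthModel:
    """Place truth SNVs uniformly in the exome and assign them to clones.

    Positions are distinct; ref is uniform over ACGT and alt uniform over
    the other three bases.  Clone assignment is multinomial with
    Dirichlet-drawn clone weights.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    exome = list(exome) if exome is not None else default_exome()
    if not exome:
        raise ValueError("exome intervals must be non-empty")
    rng = _rng(seed, "truth")
    keys = _random_keys(exome, n_variants, rng)
    weights = rng.dirichlet(np.ones(n_clones))
    clone_of = rng.choice(n_clones, size=n_variants, p=weights)
    return TruthModel(keys, clone_of, weights, exome, seed)


#: Heterogeneity profile per sample type: how many clones are active and the
#: tumor purity (parental pieces carry normal-cell contamination; clonal
#: derivatives are essentially pure).
DEFAULT_TYPE_PROFILES: dict[str, dict] = {
    "parental": {"n_active_clones": None, "purity": 0.6},  # None = all clones
    "invivo_polyclone": {"n_active_clones": 3, "purity": 0.95},
    "invitro_polyclone": {"n_active_clones": 3, "purity": 0.95},
    "monoclone": {"n_active_clones": 1, "purity": 1.0},
    "secondary_monoclone": {"n_active_clones": 1, "purity": 1.0},
}

#: Study sample counts: 7 parental tumor regions, 13 in-vivo polyclones,
#: 7 in-vitro polyclones, 19 monoclones, 4 secondary monoclones (50 total).
DEFAULT_SAMPLE_COUNTS: dict[str, int] = {
    "parental": 7,
    "invivo_polyclone": 13,
    "invitro_polyclone": 7,
    "monoclone": 19,
    "secondary_monoclone": 4,
}

_TYPE_PREFIX = {
    "parental": "Parental",
    "invivo_polyclone": "InVivoPoly",
    "invitro_polyclone": "InVitroPoly",
    "monoclone": "Mono",
    "secondary_monoclone": "SecMono",
}


@dataclass
class SampleDesign:
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_COUNTS))
    type_profiles: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TYPE_PROFILES.items()}
    )

    def __post_init__(self) -> None:
        for t, n in self.counts.items():
            if t not in DEFAULT_TYPE_PROFILES:
                raise ValueError(f"unknown sample type {t!r}")
            if n < 0:
                raise ValueError(f"negative count for {t!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())


@dataclass
class SampleSpec:
    """One simulated sample: which clones it contains and at what fraction."""

    sample_id: str
    sample_type: str
    purity: float
    clone_fractions: np.ndarray  # length n_clones; zeros for inactive clones
    index: int  # position in the study, keys the sample's RNG substream


def build_samples(
    design: SampleDesign, tm: TruthModel, seed: int
) -> list[SampleSpec]:
    """Draw the per-sample clone composition from the design profiles.

    Active-clone fractions are Dirichlet within each sample; monoclones get
    exactly one clone at fraction 1.
    """
    rng = _rng(seed, "design")
    samples: list[SampleSpec] = []
    idx = 0
    K = tm.n_clones
    for stype in DEFAULT_SAMPLE_COUNTS:  # fixed type order for determinism
        count = design.counts.get(stype, 0)
        profile = design.type_profiles[stype]
        for j in range(count):
            n_active = profile["n_active_clones"]
            fractions = np.zeros(K)
            if n_active is None or n_active >= K:
                fractions[:] = rng.dirichlet(np.ones(K))
            elif n_active == 1:
                fractions[rng.integers(K)] = 1.0
            else:
                active = rng.choice(K, size=n_active, replace=False)
                fractions[np.sort(active)] = rng.dirichlet(np.ones(n_active))
            samples.append(
                SampleSpec(
                    sample_id=f"{_TYPE_PREFIX[stype]}-{j + 1}",
                    sample_type=stype,
                    purity=float(profile["purity"]),
                    clone_fractions=fractions,
                    index=idx,
                )
            )
            idx += 1
    return samples


# ---------------------------------------------------------------------------
# site-level simulation


@dataclass
class SiteData:
    """Per-truth-variant observables for one sample."""

    sample: SampleSpec
    expected_vaf: np.ndarray
    depth: np.ndarray
    alt_reads: np.ndarray

    @property
    def present(self) -> np.ndarray:
        """Truth variants of clones active in this sample (expected VAF > 0)."""
        return self.expected_vaf > 0


def simulate_sample(
    tm: TruthModel, spec: SampleSpec, coverage: float = 80.0, seed: int = 0
) -> SiteData:
    """Draw depth and alt-read support at every truth site for one sample.

    E[VAF] = purity x clone fraction x 0.5 (heterozygous diploid);
    depth ~ Poisson(coverage); alt_reads ~ Binomial(depth, E[VAF]).
    Variants of inactive clones get alt_reads = 0.
    """
    rng = _rng(seed, "sample", spec.index)
    evaf = spec.purity * spec.clone_fractions[tm.clone_of] * 0.5
    n = len(tm)
    depth = rng.poisson(coverage, size=n)
    alt = rng.binomial(depth, evaf)
    return SiteData(spec, evaf, depth, alt)


@dataclass(frozen=True)
class PipelineBehavior:
    """Behavioral stand-in for one mapper x caller pipeline.

    The pipeline calls a truth variant when its alt-read support reaches
    ``min_alt_reads`` and a Bernoulli draw with probability
    logistic((vaf - v50) / w) succeeds; ``v50`` is the VAF of 50%
    sensitivity and ``w`` the logistic width (``w = 0`` degenerates to a
    step at v50).  False calls arrive at Poisson rate ``fp_rate`` per
    sample; with probability ``fp_shared_prob`` a false call is drawn from
    a study-wide artifact pool (a recurrent systematic error), otherwise it
    lands on a fresh random non-truth position.
    """

    pipeline_id: str
    v50: float
    w: float
    fp_rate: float
    fp_shared_prob: float = 0.0
    min_alt_reads: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.v50 < 0.5:
            raise ValueError("v50 must be in (0, 0.5)")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if not 0 <= self.fp_shared_prob <= 1:
            raise ValueError("fp_shared_prob must be in [0, 1]")


# Caller sensitivity midpoints and mapper modifiers chosen to reproduce the
# qualitative study regimes: Strelka2 most sensitive, SomaticSniper least;
# Novoalign pipelines call the most variants (higher sensitivity *and* more
# false calls), Bowtie2 the fewest.
_CALLER_V50 = {"Strelka2": 0.035, "Varscan": 0.06, "Mutect2": 0.08, "SomaticSniper": 0.12}
_MAPPER_V50_SCALE = {"Novoalign": 0.7, "Bwa": 1.0, "Bowtie2": 1.3}
_MAPPER_FP_RATE = {"Novoalign": 35.0, "Bwa": 8.0, "Bowtie2": 5.0}


def default_behaviors(fp_shared_prob: float = 0.0) -> list[PipelineBehavior]:
    """The 12 study pipelines with caller- and mapper-driven differences."""
    return [
        PipelineBehavior(
            pipeline_id=f"{m}_{c}",
            v50=_CALLER_V50[c] * _MAPPER_V50_SCALE[m],
            w=0.02,
            fp_rate=_MAPPER_FP_RATE[m],
            fp_shared_prob=fp_shared_prob,
        )
        for m in MAPPERS
        for c in CALLERS
    ]


def caller_dominant_behaviors() -> list[PipelineBehavior]:
    """Sensitivity set purely by the caller; mappers indistinguishable.

    ``w = 0`` makes detection a hard threshold on the observed VAF, so
    pipelines sharing a caller agree wherever the (shared) read support
    does — the regime where clustering recovers the caller grouping.
    """
    v50 = {"Strelka2": 0.07, "Varscan": 0.13, "Mutect2": 0.20, "SomaticSniper": 0.30}
    return [
        PipelineBehavior(f"{m}_{c}", v50=v50[c], w=0.0, fp_rate=2.0)
        for m in MAPPERS
        for c in CALLERS
    ]


def mapper_dominant_behaviors() -> list[PipelineBehavior]:
    """Sensitivity set purely by the mapper; callers indistinguishable."""
    v50 = {"Novoalign": 0.07, "Bwa": 0.15, "Bowtie2": 0.25}
    return [
        PipelineBehavior(f"{m}_{c}", v50=v50[m], w=0.0, fp_rate=2.0)
        for m in MAPPERS
        for c in CALLERS
    ]


def make_artifact_pool(
    tm: TruthModel, size: int, seed: int
) -> list[VariantKey]:
    """Study-wide pool of recurrent artifact sites, disjoint from truth."""
    rng = _rng(seed, "artifacts")
    truth = set(tm.variants)
    pool: list[VariantKey] = []
    while len(pool) < size:
        for key in _random_keys(tm.exome, size - len(pool), rng):
            if key not in truth:
                pool.append(key)
    return pool


def apply_pipeline(
    site: SiteData,
    tm: TruthModel,
    behavior: PipelineBehavior,
    artifact_pool: Sequence[VariantKey],
    seed: int,
    coverage: float = 80.0,
) -> CallSet:
    """Produce one pipeline's call set for one simulated sample.

    Called truth sites with depth < 10 are dropped (they could not survive
    the downstream depth filter anyway, mirroring callers' own floors).
    False-positive records get plausible low-VAF metadata.  The RNG
    substream is keyed by the pipeline's *name*, so adding or reordering
    pipelines never perturbs another pipeline's calls.
    """
    pipeline_tag = zlib.crc32(behavior.pipeline_id.encode())
    rng = _rng(seed, "pipeline", site.sample.index, pipeline_tag)
    depth, alt = site.depth, site.alt_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    if behavior.w <= 0:
        p_detect = (vaf >= behavior.v50).astype(float)
    else:
        p_detect = 1.0 / (1.0 + np.exp(-(vaf - behavior.v50) / behavior.w))
    called = (
        (alt >= behavior.min_alt_reads)
        & (rng.random(len(vaf)) < p_detect)
        & (depth >= 10)
    )

    records: dict[VariantKey, CallRecord] = {}
    for i in np.flatnonzero(called):
        key = tm.variants[i]
        records[key] = CallRecord(key, int(depth[i]), int(alt[i]), float(vaf[i]))

    truth_set = set(tm.variants)
    n_fp = rng.poisson(behavior.fp_rate)
    for _ in range(n_fp):
        if artifact_pool and rng.random() < behavior.fp_shared_prob:
            key = artifact_pool[rng.integers(len(artifact_pool))]
        else:
            key = None
            while key is None:
                cand = _random_keys(tm.exome, 1, rng)[0]
                if cand not in truth_set:
                    key = cand
        if key in records:
            continue
        d = max(10, int(rng.poisson(coverage)))
        fvaf = float(rng.uniform(0.05, 0.25))
        a = min(d, int(rng.binomial(d, fvaf)))
        records[key] = CallRecord(key, d, a, a / d if d else -1.0)

    return CallSet(
        behavior.pipeline_id,
        site.sample.sample_id,
        site.sample.sample_type,
        records.values(),
    )


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class StudyConfig:
    """Parameters of one simulated study (defaults emulate the real design)."""

    n_variants: int = 4800
    n_clones: int = 8
    coverage: float = 80.0
    seed: int = 0
    design: SampleDesign = field(default_factory=SampleDesign)
    behaviors: list[PipelineBehavior] = field(default_factory=default_behaviors)
    artifact_pool_size: int = 500


_CONFIG_KEYS = {
    "n_variants", "n_clones", "coverage", "seed", "counts", "purities",
    "behaviors", "artifact_pool_size", "fp_shared_prob",
}


def load_config(path: str | Path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    design = SampleDesign()
    if "counts" in raw:
        design.counts = {t: int(n) for t, n in raw["counts"].items()}
        design.__post_init__()
    if "purities" in raw:
        for t, p in raw["purities"].items():
            if t not in design.type_profiles:
                raise ValueError(f"unknown sample type in purities: {t!r}")
            design.type_profiles[t]["purity"] = float(p)
    if "behaviors" in raw:
        behaviors = [PipelineBehavior(**b) for b in raw["behaviors"]]
    else:
        behaviors = default_behaviors(fp_shared_prob=float(raw.get("fp_shared_prob", 0.0)))
    return StudyConfig(
        n_variants=int(raw.get("n_variants", 4800)),
        n_clones=int(raw.get("n_clones", 8)),
        coverage=float(raw.get("coverage", 80.0)),
        seed=int(raw.get("seed", 0)),
        design=design,
        behaviors=behaviors,
        artifact_pool_size=int(raw.get("artifact_pool_size", 500)),
    )


@dataclass
class StudyResult:
    """In-memory product of one simulated study."""

    config: StudyConfig
    truth_model: TruthModel
    samples: list[SampleSpec]
    callsets: dict[tuple[str, str], CallSet]  # (pipeline_id, sample_id) -> calls
    truth_keys: dict[str, set[VariantKey]]  # sample_id -> truth variants present
    truth_records: dict[str, list[CallRecord]]  # for truth VCF export

    @property
    def sample_types(self) -> dict[str, str]:
        return {s.sample_id: s.sample_type for s in self.samples}


def simulate_study(config: StudyConfig | None = None) -> StudyResult:
    """Run the full generator in memory: truth, samples, and all call sets."""
    config = config or StudyConfig()
    tm = generate_truth(config.n_variants, None, config.n_clones, config.seed)
    samples = build_samples(config.design, tm, config.seed)
    pool = make_artifact_pool(tm, config.artifact_pool_size, config.seed)

    callsets: dict[tuple[str, str], CallSet] = {}
    truth_keys: dict[str, set[VariantKey]] = {}
    truth_records: dict[str, list[CallRecord]] = {}
    for spec in samples:
        site = simulate_sample(tm, spec, config.coverage, config.seed)
        present = np.flatnonzero(site.present)
        truth_keys[spec.sample_id] = {tm.variants[i] for i in present}
        truth_records[spec.sample_id] = [
            CallRecord(
                tm.variants[i],
                int(site.depth[i]),
                int(site.alt_reads[i]),
                float(site.alt_reads[i] / site.depth[i]) if site.depth[i] > 0 else -1.0,
            )
            for i in present
        ]
        for behavior in config.behaviors:
            cs = apply_pipeline(site, tm, behavior, pool, config.seed, config.coverage)
            callsets[(behavior.pipeline_id, spec.sample_id)] = cs
    return StudyResult(config, tm, samples, callsets, truth_keys, truth_records)


def generate_study(
    config: StudyConfig | None = None, outdir: str | Path = "study"
) -> StudyResult:
    """Simulate a study and write its artifacts to disk.

    Emits one VCF per (pipeline, sample) under ``vcf/``, one truth VCF per
    sample under ``truth/``, a manifest TSV, the exome BED, and a
    provenance JSON with the seed and all parameters.  Re-running with the
    same config produces byte-identical files.
    """
    import pandas as pd

    config = config or StudyConfig()
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    result = simulate_study(config)

    rows = []
    for spec in result.samples:
        truth_path = outdir / "truth" / f"{spec.sample_id}.truth.vcf"
        truth_cs = CallSet(
            "truth", spec.sample_id, spec.sample_type,
            result.truth_records[spec.sample_id],
        )
        write_vcf(truth_cs, truth_path)
        for behavior in config.behaviors:
            cs = result.callsets[(behavior.pipeline_id, spec.sample_id)]
            vcf_path = outdir / "vcf" / f"{behavior.pipeline_id}__{spec.sample_id}.vcf"
            write_vcf(cs, vcf_path)
            # manifest paths are relative to the study directory so a study
            # is relocatable and byte-identical across output locations
            rows.append(
                {
                    "pipeline_id": behavior.pipeline_id,
                    "sample_id": spec.sample_id,
                    "sample_type": spec.sample_type,
                    "vcf_path": str(vcf_path.relative_to(outdir)),
                    "truth_vcf": str(truth_path.relative_to(outdir)),
                    "scored": True,
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.tsv")
    write_bed(result.truth_model.exome, outdir / "exome.bed")

    provenance = {
        "seed": config.seed,
        "n_variants": config.n_variants,
        "n_clones": config.n_clones,
        "coverage": config.coverage,
        "artifact_pool_size": config.artifact_pool_size,
        "counts": config.design.counts,
        "type_profiles": config.design.type_profiles,
        "behaviors": [asdict(b) for b in config.behaviors],
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    return result


def purity_sweep(
    purities: Sequence[float] = (0.2, 0.5, 1.0),
    n_variants: int = 1500,
    n_samples: int = 4,
    coverage: float = 80.0,
    seed: int = 0,
    behaviors: list[PipelineBehavior] | None = None,
) -> dict[float, StudyResult]:
    """One clonal mini-study per purity level (the coverage-mixing design).

    Each study holds ``n_samples`` monoclonal samples of a single clone at
    the given purity, so every truth variant's expected VAF is
    purity x 0.5.  Used to measure how recall responds to purity.
    """
    out: dict[float, StudyResult] = {}
    for purity in purities:
        design = SampleDesign(counts={"monoclone": n_samples})
        design.type_profiles["monoclone"]["purity"] = float(purity)
        config = StudyConfig(
            n_variants=n_variants,
            n_clones=1,
            coverage=coverage,
            seed=seed,
            design=design,
            behaviors=behaviors or default_behaviors(),
        )
        out[float(purity)] = simulate_study(config)
    return out
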