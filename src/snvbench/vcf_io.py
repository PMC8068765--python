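"""Reading, filtering and writing of somatic SNV call sets.

A *call set* is the list of single-nucleotide variants one pipeline
(mapper + variant caller) reported for one tumor sample.  Variant identity
throughout the package is the tuple (contig, 1-based position, ref, alt):
genotype, quality and annotations play no role in cross-pipeline set
algebra.  Only biallelic SNV alleles are retained; multiallelic records are
split into one call per ALT allele and non-SNV alleles (indels, MNVs,
symbolic alleles) are dropped and counted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

#: Mapper and caller vocabularies used to decompose "<mapper>_<caller>"
#: pipeline identifiers (the study design: 3 mappers x 4 callers).
MAPPERS = ("Bwa", "Bowtie2", "Novoalign")
CALLERS = ("Mutect2", "Varscan", "SomaticSniper", "Strelka2")

SAMPLE_TYPES = (
    "parental",
    "invivo_polyclone",
    "invitro_polyclone",
    "monoclone",
    "secondary_monoclone",
)

#: The twelve mapper_caller pipeline identifiers, mapper-major order.
DEFAULT_PIPELINES = tuple(f"{m}_{c}" for m in MAPPERS for c in CALLERS)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a single-nucleotide variant.

    Positions are 1-based as in VCF and are never converted.  ``ref`` and
    ``alt`` must be single bases in {A, C, G, T} with ``alt != ref``.
    """

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"SNV alleles must be single bases in ACGT, got "
                f"ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"alt must differ from ref ({self.ref!r})")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class CallRecord:
    """One SNV call with its read-support metadata.

    ``depth`` is the tumor-sample read depth at the site; ``alt_reads`` and
    ``vaf`` are -1 when the caller did not report them.
    """

    key: VariantKey
    depth: int
    alt_reads: int = -1
    vaf: float = -1.0
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.alt_reads >= 0 and self.depth >= 0 and self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth}) "
                f"at {self.key}"
            )


class CallSet:
    """The variants one pipeline detected in one sample.

    Records are keyed by :class:`VariantKey`; duplicates are rejected.
    ``info`` carries bookkeeping from parsing/filtering (dropped non-SNV
    alleles, per-reason filter removals).
    """

    def __init__(
        self,
        pipeline_id: str,
        sample_id: str,
        sample_type: str,
        records: Iterable[CallRecord] = (),
        info: dict | None = None,
    ) -> None:
        if sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {sample_type!r}; expected one of {SAMPLE_TYPES}"
            )
        self.pipeline_id = pipeline_id
        self.sample_id = sample_id
        self.sample_type = sample_type
        self.info: dict = dict(info) if info else {}
        self._records: dict[VariantKey, CallRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: CallRecord) -> None:
        if rec.key in self._records:
            raise ValueError(
                f"duplicate variant {rec.key} in call set "
                f"({self.pipeline_id}, {self.sample_id})"
            )
        self._records[rec.key] = rec

    @property
    def records(self) -> list[CallRecord]:
        return list(self._records.values())

    def keys(self) -> set[VariantKey]:
        return set(self._records)

    def get(self, key: VariantKey) -> CallRecord | None:
        return self._records.get(key)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._records

    def __iter__(self) -> Iterator[CallRecord]:
        return iter(self._records.values())

    @property
    def mapper(self) -> str:
        return split_pipeline_id(self.pipeline_id)[0]

    @property
    def caller(self) -> str:
        return split_pipeline_id(self.pipeline_id)[1]

    def replace_records(self, records: Iterable[CallRecord], info: dict | None = None) -> "CallSet":
        return CallSet(self.pipeline_id, self.sample_id, self.sample_type, records, info)


def split_pipeline_id(
    pipeline_id: str,
    mappers: tuple[str, ...] = MAPPERS,
    callers: tuple[str, ...] = CALLERS,
) -> tuple[str, str]:
    """Decompose ``"<mapper>_<caller>"`` against the declared vocabularies."""
    mapper, sep, caller = pipeline_id.partition("_")
    if not sep or mapper not in mappers or caller not in callers:
        raise ValueError(
            f"pipeline_id {pipeline_id!r} does not decompose as <mapper>_<caller> "
            f"with mapper in {mappers} and caller in {callers}"
        )
    return mapper, caller


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_header(path: Path) -> None:
    """Fail fast with the offending line when the VCF header is absent/garbled."""
    with _open_text(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("##fileformat=VCF"):
            raise ValueError(
                f"{path}: not a VCF file; first line is {first[:80]!r} "
                "(expected '##fileformat=VCFv4.x')"
            )
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("#CHROM"):
                return
            if not line.startswith("##"):
                raise ValueError(
                    f"{path}: garbled header at line {lineno}: {line[:80]!r} "
                    "(no #CHROM column line found)"
                )
    raise ValueError(f"{path}: header has no #CHROM line")


_INT_MISSING = -2147483648  # htslib sentinel surfaced by cyvcf2


def parse_vcf(
    path: str | Path,
    pipeline_id: str,
    sample_id: str,
    sample_type: str,
    tumor_sample: str | None = None,
    strip_chr_prefix: bool = False,
) -> CallSet:
    """Parse a VCF into a :class:`CallSet` of biallelic SNV calls.

    Multiallelic records are split into one record per ALT allele.  Depth is
    the tumor sample's FORMAT/DP (fallback INFO/DP), alt_reads the tumor
    FORMAT/AD entry for the allele, and VAF FORMAT/AF when present, else
    alt_reads/depth.  The tumor column is ``tumor_sample`` when given,
    otherwise the last sample column (tumor-last convention).  Records whose
    AD exceeds DP are kept with a warning and their VAF marked missing.
    Dropped non-SNV allele counts end up in ``info["dropped_non_snv"]``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_header(path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if tumor_sample is not None:
        if tumor_sample not in samples:
            raise ValueError(
                f"{path}: tumor sample {tumor_sample!r} not among VCF samples {samples}"
            )
        tumor_idx = samples.index(tumor_sample)
    else:
        tumor_idx = len(samples) - 1  # tumor-last convention

    records: list[CallRecord] = []
    dropped = 0
    warned_ad = False
    for var in vcf:
        contig = var.CHROM
        if strip_chr_prefix and contig.startswith("chr"):
            contig = contig[3:]
        ref = var.REF.upper()

        depth = _INT_MISSING
        ad = None
        af = None
        if samples:
            dp_arr = var.format("DP")
            if dp_arr is not None:
                depth = int(dp_arr[tumor_idx][0])
            ad_arr = var.format("AD")
            if ad_arr is not None:
                ad = ad_arr[tumor_idx]
            af_arr = var.format("AF")
            if af_arr is not None:
                af = af_arr[tumor_idx]
        if depth == _INT_MISSING or depth < 0:
            info_dp = var.INFO.get("DP")
            depth = int(info_dp) if info_dp is not None else -1

        filter_status = var.FILTER if var.FILTER is not None else "PASS"

        for alt_idx, alt in enumerate(var.ALT):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                dropped += 1
                continue
            key = VariantKey(contig, var.POS, ref, alt)

            alt_reads = -1
            if ad is not None and len(ad) > alt_idx + 1:
                val = int(ad[alt_idx + 1])
                if val >= 0 and val != _INT_MISSING:
                    alt_reads = val
            vaf = -1.0
            if af is not None and len(af) > alt_idx:
                val = float(af[alt_idx])
                if 0.0 <= val <= 1.0:
                    vaf = val
            if vaf < 0 and alt_reads >= 0 and depth > 0:
                vaf = alt_reads / depth

            if alt_reads >= 0 and depth >= 0 and alt_reads > depth:
                if not warned_ad:
                    logger.warning(
                        "%s: AD exceeds DP at %s:%d (kept, VAF set missing)",
                        path, contig, var.POS,
                    )
                    warned_ad = True
                alt_reads = -1
                vaf = -1.0

            records.append(
                CallRecord(
                    key=key,
                    depth=depth,
                    alt_reads=alt_reads,
                    vaf=vaf,
                    filter_status=filter_status,
                )
            )
    return CallSet(
        pipeline_id, sample_id, sample_type, records,
        info={"dropped_non_snv": dropped, "source": str(path)},
    )


def apply_filters(
    cs: CallSet, min_depth: int = 10, pass_only: bool = True
) -> CallSet:
    """Apply the depth floor and FILTER-status filter.

    Retains records with ``depth >= min_depth`` and, when ``pass_only``,
    FILTER in {PASS, "."}.  Records with missing depth (-1) fail the depth
    filter.  The returned call set's ``info["filter_removals"]`` maps reason
    ("low_depth", "non_pass") to removed counts; applying the same filter
    twice is a no-op.
    """
    kept: list[CallRecord] = []
    removed = {"low_depth": 0, "non_pass": 0}
    missing_depth_seen = False
    for rec in cs:
        if rec.depth < min_depth:
            removed["low_depth"] += 1
            if rec.depth < 0 and not missing_depth_seen:
                logger.warning(
                    "(%s, %s): records with missing depth fail the depth filter",
                    cs.pipeline_id, cs.sample_id,
                )
                missing_depth_seen = True
            continue
        if pass_only and rec.filter_status not in ("PASS", "."):
            removed["non_pass"] += 1
            continue
        kept.append(rec)
    info = dict(cs.info)
    info["filter_removals"] = removed
    return cs.replace_records(kept, info)


def write_vcf(cs: CallSet, path: str | Path) -> None:
    """Write a minimal VCF 4.2 that round-trips through :func:`parse_vcf`.

    One sample column (named after the call set's sample), FORMAT GT:DP:AD:AF;
    records sorted by (contig, position, ref, alt).  Missing alt_reads/VAF
    are written as ".".
    """
    path = Path(path)
    recs = sorted(cs, key=lambda r: (r.key.contig, r.key.position, r.key.ref, r.key.alt))
    contigs = sorted({r.key.contig for r in recs})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + cs.sample_id,
    ]
    for r in recs:
        if r.alt_reads >= 0 and r.depth >= 0:
            ad = f"{r.depth - r.alt_reads},{r.alt_reads}"
        else:
            ad = "."
        dp = str(r.depth) if r.depth >= 0 else "."
        af = f"{r.vaf:.6g}" if r.vaf >= 0 else "."
        lines.append(
            f"{r.key.contig}\t{r.key.position}\t.\t{r.key.ref}\t{r.key.alt}"
            f"\t.\t{r.filter_status}\t.\tGT:DP:AD:AF\t0/1:{dp}:{ad}:{af}"
        )
    path.write_text("\n".join(lines) + "\n")


MANIFEST_COLUMNS = ("pipeline_id", "sample_id", "sample_type", "vcf_path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated manifest of (pipeline, sample) call-set files.

    Required columns: pipeline_id, sample_id, sample_type, vcf_path.
    Optional: truth_vcf (per-sample truth for simulation runs), scored
    (boolean; samples excluded from metric summaries keep participating in
    validation).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
    if bad:
        raise ValueError(f"manifest {path} has unknown sample types: {sorted(bad)}")
    if "scored" in df.columns:
        df["scored"] = df["scored"].str.lower().isin(("true", "1", "yes"))
    else:
        df["scored"] = True
    dup = df.duplicated(subset=["pipeline_id", "sample_id"])
    if dup.any():
        pairs = df.loc[dup, ["pipeline_id", "sample_id"]].to_records(index=False)
        raise ValueError(f"manifest {path} has duplicate (pipeline, sample) pairs: {list(pairs)}")
    # relative paths are taken relative to the manifest's own directory
    base = Path(path).parent
    for col in ("vcf_path", "truth_vcf"):
        if col in df.columns:
            df[col] = [
                p if Path(p).is_absolute() else str(base / p) for p in df[col]
            ]
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
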