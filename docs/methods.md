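# Methods

## The evaluation problem

Somatic SNV calling on tumor/normal pairs has no per-study ground truth.
When a study sequences many samples derived from one tumor, recurrence of a
variant across samples can stand in for truth: a caller hallucinating the
*same* base substitution at the *same* position in two independently
prepared and sequenced samples is unlikely, while a genuine somatic variant
carried by a clone present in several samples will recur. `snvbench`
formalizes this as a validation rule and builds the whole evaluation —
per-pipeline scores, similarity structure, union-combination optimization —
on top of it.

## Variant identity and filtering

A variant is the tuple (contig, 1-based position, ref, alt), single-base
alleles only; genotype, quality and annotations are ignored because the
framework compares *lists* of variants across pipelines. Multiallelic VCF
records are split per ALT allele; indels, MNVs and symbolic alleles are
dropped and counted. Filtering keeps records with tumor depth ≥ 10
(`min_depth`, the floor applied uniformly to all pipelines for fairness)
and FILTER in {PASS, "."}. Records with missing depth fail the depth
filter: letting unknowable records through would defeat a uniform depth
floor. The depth floor is applied to the tumor sample's depth; the tumor
column defaults to the last sample column of the VCF and can be named
explicitly, since callers disagree on column order. Contig names are
compared verbatim, with an opt-in `strip_chr_prefix` because mixed
`chr1`/`1` conventions would silently zero every overlap.

## Validation and classification

The detection index maps each variant to the set of (pipeline, sample)
pairs that called it. A variant is **validated** when detected in
≥ `min_samples` samples (default 2) and by ≥ `min_pipelines` pipelines
(default 1): detections pool across pipelines, so pipeline A finding a
variant in sample 1 and pipeline B finding it in sample 2 corroborate each
other. The stricter same-pipeline reading is available by raising
`min_pipelines`; the two axes are deliberately independent parameters and
are never merged.

For one pipeline on one sample: TP = calls ∩ validated, FP = calls \
validated. False negatives default to **per-sample scope**: only validated
variants that *some* pipeline detected in that sample count as missable
there. Samples genuinely differ in the variants they carry, so charging a
monoclone's pipeline for a variant private to a different clone would
measure the biology, not the pipeline. Global scope (all validated
variants) is kept as an option for sensitivity analysis.

Undefined ratios (zero denominators) are reported as missing, never as 0,
and aggregation means skip them — otherwise zero-call edge cases would
drag mapper/caller means down. F1 is computed from integer counts
(2TP/(2TP+FP+FN)), not from rounded precision/recall. Mapper-level and
caller-level summaries are per-sample means over the 4 callers sharing a
mapper (respectively 3 mappers sharing a caller). Per-sample metric
averaging is the default throughout; pooled-count precision/recall across
samples is available (`truth_eval.pooled_precision`) where a single
per-pipeline number is wanted.

## Similarity and clustering

For one sample type, every (sample, variant) detection event seen by any
pipeline is a row of a 0/1 incidence matrix with one column per pipeline —
events are pooled within the type rather than averaged over per-sample
matrices, so one matrix describes one sample type. Column pairs are
compared with cosine, Jaccard or Pearson similarity (binary vectors;
Jaccard ≤ cosine always holds). All-zero columns leave their pairs
undefined (missing), and clustering refuses incomplete matrices rather
than guessing. Pipelines are clustered agglomeratively with average
linkage (UPGMA) on distance 1 − similarity; the linkage method is a
package choice — nothing in the statistic dictates one. Leaf order is
deterministic: children of each node are ordered by their smallest
original column index, so exact ties resolve to input order.

## Union combinations

The union of k pipelines' call sets is scored exactly like a pipeline,
against the *same* validated set computed once from individual pipelines —
unions never feed back into validation, which would make combination
scores self-referential. All 2ⁿ−1 non-empty subsets are enumerated (4095
for 12 pipelines). Scoring uses per-variant detection bitmasks and a
sum-over-subsets transform, so the full sweep over 50 samples takes
seconds and memory stays bounded by one sample's call sets. Best-F1 ties
break toward smaller combinations, then lexicographic id — parsimony,
because union gains saturate with size. Per-sample winners are tallied by
sample type for sizes 1–3 (configurable), and a long-format best-F1-per-
size table supports distribution plots; no unimodality of F1 in size is
assumed or asserted.

Exact monotonicity properties of unions, which the test suite asserts for
every add-one nested pair (and hence, transitively, for all nested pairs):
TP and FP never decrease, and — because TP + FN is fixed per sample once
the validated set is — recall never decreases. Pointwise precision
monotonicity is **not** a theorem and is not asserted: adding a
high-precision pipeline to a low-precision combination raises the union's
precision (observed for ~1% of nested pairs in simulated studies). The
precision/recall trade-off is real in aggregate, and that is the form the
suite asserts: mean precision per combination size is non-increasing in
size.

## The synthetic study generator

The generator produces *calls*, not reads. Re-running real aligners and
callers on simulated reads is out of scope; the behavioral model below is
the minimal structure that reproduces every phenomenon the downstream
analysis measures (count differences, precision/recall trade-off,
similarity structure, combination gains, validation failure under
recurrent artifacts).

**Truth.** ~4800 SNVs placed uniformly without positional collision in a
toy exome (10 contigs × 10 intervals × 10 kb = 1 Mb; no reference genome
is needed because ref bases are simulated). Each variant belongs to one of
K = 8 clones, assigned multinomially with Dirichlet-drawn clone weights.
Uniform placement is a simplification: no mutation-signature or
context-dependent model is applied.

**Samples.** 50 samples in five types matching the emulated design —
7 parental multi-region pieces, 13 in-vivo polyclones, 7 in-vitro
polyclones, 19 monoclones, 4 secondary monoclones. Heterogeneity profile
per type: parental samples contain all K clones (Dirichlet fractions) at
purity 0.6 (normal contamination); polyclones 3 clones at purity 0.95;
monoclones exactly one clone at purity 1.0. Expected VAF is
purity × clone fraction × 0.5 — heterozygous diploid, no copy-number or
LOH modeling, because the purity argument is linear in allele fraction
and needs none. Site depth ~ Poisson(80) (the emulated coverage range is
50–100×); alt reads ~ Binomial(depth, E[VAF]).

**Pipelines.** Each of the 12 mapper × caller pipelines has a behavioral
profile: it calls a truth site when alt reads ≥ `min_alt_reads` (3) and a
Bernoulli draw with probability logistic((VAF − v50)/w) succeeds. Caller
sensitivity midpoints v50 = {Strelka2 0.035, Varscan 0.06, Mutect2 0.08,
SomaticSniper 0.12} scaled by mapper factors {Novoalign 0.7, Bwa 1.0,
Bowtie2 1.3}, logistic width w = 0.02. False calls arrive at Poisson rate
λ per sample ({Novoalign 35, Bwa 8, Bowtie2 5}) at random non-truth
positions; with probability ρ (`fp_shared_prob`, default 0) a false call
is drawn instead from a study-wide 500-site artifact pool, modeling
recurrent systematic errors. These values reproduce the qualitative
regimes of interest — Novoalign-like pipelines find the most variants
(highest recall, lowest precision), Bowtie2-like the fewest, Strelka2 the
most sensitive caller and SomaticSniper the least — though absolute
precision in simulation runs higher than on real tumors, where artifact
loads are heavier than a flat Poisson rate.

Two preset behavior sets support the clustering analyses:
`caller_dominant_behaviors` (v50 set purely by caller) and
`mapper_dominant_behaviors` (purely by mapper). They use w = 0, i.e. a
hard threshold on the observed VAF, so pipelines sharing the dominant
token agree wherever the (shared) read support does; with the logistic
draw, independent Bernoulli noise would mask the group structure that
deterministic thresholding makes recoverable.

**Purity mixing.** `purity_from_mixing(t, n) = t/(t+n)` is the call-level
analog of pooling a t× tumor read set with an n× normal read set
(20×+80× → 20%, 80×+80× → 50%, unmixed → 100%). `purity_sweep` builds
clonal mini-studies at a series of purities to measure recall against
purity; recall declines as purity falls because expected VAF scales with
purity and drops below pipeline sensitivity midpoints — steepest for the
least sensitive profiles.

**Randomness.** All draws flow from one master seed through named
substreams (truth, design, per-sample, per-pipeline keyed by a CRC of the
pipeline name, artifact pool), so identical configurations produce
byte-identical outputs and adding or reordering pipelines does not perturb
any other pipeline's calls. Manifests store paths relative to the study
directory, keeping studies relocatable and byte-comparable.

## What the simulation does and does not show

Truth-known simulation lets the suite verify the validation statistic
itself: with unshared false calls (ρ = 0), per-pipeline validation-based
precision tracks truth-based precision closely (within 0.05 pooled over a
50-sample, 5000-variant study — the rare disagreements are truth variants
seen in only one sample, charged as FP by validation, and chance FP
collisions); with ρ = 0.9 the artifact pool recurs across samples, passes
validation, and validation-based precision exceeds truth-based precision
for every pipeline — the stated failure mode of cross-sample validation.
Because the generator omits mapper-specific alignment artifacts, sequence
context effects, and realistic error processes, passing these tests shows
the *framework* is correct and the *statistic* behaves as designed, not
that any particular real pipeline has these scores.

## Problem sizes and numerical choices

The test suite runs simulated studies at the emulated design size
(12 × 50, ~5000 truth variants) for the study-level properties and smaller
configurations (hundreds of variants, a handful of samples) for unit
behavior; the full combination sweep is exact, never sampled. Tolerances:
Monte-Carlo means are checked within 3 binomial standard errors;
floating-point metric identities within 1e-12; monotonicity assertions
are exact on integer counts. Degenerate inputs (empty call sets, empty
validated sets, all-zero similarity columns, all-missing F1) are
propagated as missing values or explicit refusals, never silently coerced.
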