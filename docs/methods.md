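# Methods

`teleoarray` re-implements, as a tested library, the desk-side computational
workflow behind a custom one-color 60-mer oligo microarray for a non-model
teleost (the motivating application is expression profiling of mandibular
prognathism — lower-jaw protrusion — in juvenile European sea bass): EST
clustering into a unique-transcript catalog, dual probe selection,
homology-based annotation, spike-in-guided normalization and array QC,
SAM differential expression with probe-to-transcript aggregation, natural
antisense transcript (NAT) inference, GO over-representation against a
custom array background, and efficiency-corrected qPCR cross-validation.
This note records the models, the defaults and why, and the choices made
where the design was genuinely open.

## EST clustering (`clustering`)

Two sequences belong to the same cluster when their best end-free (overlap)
alignment spans at least **40 bp** at an identity of at least **90%**; both
thresholds are inclusive. Clusters are the single-linkage transitive closure
of accepted pairs, so membership is a partition of the input and raising
either threshold can only refine it.

Open choices and substitutions:

* **Candidate screen.** Pairs are pre-screened by exact shared k-mers
  (default k = 16, both orientations) instead of a BLAST pass. This is
  deterministic and needs no external binary. At 90% identity a 40 bp
  overlap has at most 4 mismatches and therefore a mismatch-free stretch of
  ≥ 8 bp; k = 16 is a pragmatic screen, not a mathematical superset
  guarantee at high divergence — lower k if that matters.
* **Alignment scoring.** match +1, mismatch −1, linear gap −2, free end
  gaps (biopython `PairwiseAligner`). Identity is matches over aligned
  columns of the overlap region, *including internal gaps in the
  denominator* — an explicit, testable convention; whether terminal gaps
  count is genuinely ambiguous and we chose the overlap-region convention.
* **Orientation.** Reverse-complement overlaps are considered (5'-sequenced
  ESTs carry orientation errors); the higher-scoring orientation is judged.
* **Consensus.** A majority-vote layout: the longest member is the
  backbone, remaining members are overlap-aligned into the column layout,
  and each column is called by vote with ties broken by first-seen base.
  This is a deliberate stand-in for an OLC assembler: exact on noiseless
  tiling fragments (tested), approximate on conflicting data. Consensus
  length is never shorter than the longest member.

The test suite checks the partition against an independent brute-force
oracle (a hand-written semi-global dynamic program plus union-find) on
catalogs of up to 50 sequences.

## Probe selection (`probes`)

Each transcript — assumed to be the sense strand — receives up to two
non-overlapping 60-mer probes as near as possible to the 3' end, indexed
`_1` (more 3'-proximal) and `_2`. The vendor's proprietary probe scorer is
not reproducible, so windows are screened with transparent substitutes, all
config-exposed (`DesignParameters`):

| parameter | default | rationale |
|---|---|---|
| GC fraction | [0.35, 0.60] | hybridization uniformity |
| homopolymer cap | runs ≤ 7 | synthesis/hybridization artifacts |
| ambiguous bases | none | probes must be fully specified |
| cross-hyb cap | 0 shared 15-mers | 15-mer sharing with any other transcript proxies cross-hybridization |
| poly-A mask | 3' runs ≥ 10 A | prevents degenerate 3' windows |

Selection is greedy from the 3' end: `_1` is the most 3'-proximal passing
window, `_2` the most 3'-proximal passing window disjoint from it — which
is also the lexicographic optimum over all disjoint passing pairs (verified
by exhaustive search in tests). One passing window yields a single probe;
none yields a logged failure. On synthetic catalogs of ≥ 200 nt transcripts
the design success rate exceeds 99%.

The `_1`-is-more-3' convention is our own; nothing upstream defines index
order.

## Annotation and id mapping (`annotation`)

Hit tables are 12-column BLAST tabular files. Strand sign is −1 when
exactly one of the coordinate pairs is reversed; a 13th `qframe` column,
when present, takes precedence (translated searches). A transcript is
**protein-annotated** when any protein-database hit has e < 1e−3,
otherwise **nucleotide-only** when any nucleotide hit has e < 1e−5,
otherwise **unannotated**; both cutoffs are strict as printed. Best hits
break ties by minimum e-value, then maximum bit score, then lexicographic
subject id — the source protocol is silent on ties, so the rule is fixed
and row-order independent.

GO-slim rollups consume an explicit many-to-many term → (slim, namespace)
map; terms missing from the map are returned as unmapped rather than
silently dropped. Model-organism id mapping supports the four routes
(direct-to-human, via-stickleback-to-human, direct-to-zebrafish,
via-stickleback-to-zebrafish); indirect routes compose best hits, and both
raw and unique-id counts are reported because many transcripts share a
model gene.

## Normalization and QC (`normalize`)

Intensities are positive linear values with binary detection flags (1 =
spot above local background; 0 is treated as missing downstream).

* **Quantile normalization** forces every column onto the per-rank mean
  distribution; ties receive the mean of the rank means they occupy, so
  constant columns are handled. It is idempotent and rank-preserving (up to
  ties) and removes per-array monotone distortions exactly when arrays
  share an underlying order — the property the synthetic generator's
  affine log-scale distortions are built to exercise.
* **Cyclic loess** (pairwise M-vs-A, span 0.4, 3 cycles, statsmodels
  lowess) is implemented as the comparator; **median scaling** and
  **none** complete the candidate set.
* **Method selection** scores each candidate by spike-in flatness: the mean
  CV across arrays of the spike-in control rows, which were spiked at fixed
  concentrations and should be flat after good normalization. Lowest CV
  wins; ties keep listing order (quantile first).
* **QC surfaces.** (i) Hybridization success: per-probe flag counts; "at
  least half of the experiments" uses the ceiling for odd counts — a
  conservative, config-exposed reading. (ii) Probe-pair concordance: per
  transcript and sample, FC = max(I1, I2)/min(I1, I2) on the linear
  normalized scale (so FC ≥ 1), with the "< 2" summary strict; plus the
  per-transcript Pearson r between the two probes across samples.
  (iii) Replicate correlation: pairwise Pearson, on log2 values by default
  (the scale is not documented upstream; linear is available).

A minimal GEO series-matrix reader is included so the pipeline can run on
archived series; it is a plain-text parser, not a GEO client.

## Differential expression (`sam`)

* **Missing-value filter:** a probe is removed when it has more than
  `max_missing_per_condition` (default 2) flag-0 values in either
  condition. Residual missing entries are imputed by the within-condition
  probe mean (fallback: overall mean); the upstream protocol is silent on
  imputation.
* **SAM statistic:** d = (mean_deformed − mean_normal)/(s + s0) on log2
  intensities, with s the pooled standard error
  `sqrt((1/n1 + 1/n2) (SS1 + SS2)/(n1 + n2 − 2))`. The fudge factor s0
  defaults to "auto": the percentile of s (0, 5, …, 100) minimizing the
  coefficient of variation of the per-bin MAD of d across s-quantile bins —
  the original recipe — with a positive floor guarding zero-variance probes.
* **Permutations:** all balanced label reassignments when their number is
  ≤ 1000 (e.g. C(8,4) = 70 for 4 vs 4, fully deterministic), otherwise
  seeded Monte-Carlo draws (default 500).
* **Calling:** expected order statistics d̄₍ᵢ₎ are permutation means; for a
  threshold delta the upper cutoff is the smallest observed d above the
  band in the d̄ ≥ 0 region (symmetrically below), and all d beyond the
  cutoffs are called. FDR = π0 × (median permutation false calls)/calls,
  with π0 = min(1, fraction of observed d inside the permutation
  interquartile band / 0.5). Delta is tuned to the largest call set with
  estimated FDR at or below the target (default 5%). Per-probe q-values are
  the smallest estimated FDR at which the probe is called. The delta scan
  uses at most ~400 grid points on platform-scale inputs, which only
  coarsens q-value granularity, never the call set at the tuned delta's
  neighbors' expense.
  One quirk is inherited from the median-based estimator: single-probe call
  sets can carry an estimated FDR of exactly 0, so a null dataset
  occasionally yields 1–3 calls; across seeds the typical (median) null
  call count is 0.
* **Fold changes** are reported both as linear ratios (deformed/normal)
  and in the signed convention (−1/ratio when ratio < 1), since both are
  conventional. Statistics are computed on log2 values, fold changes on
  linear means.
* **Aggregation:** significant probes collapse to unique transcripts with
  categories both-probe, single (other probe filtered), single (other probe
  tested but not called), and single-probe-on-platform; the bookkeeping
  conserves 2 × both + singles = significant probes.
* **Tissue-dilution model:** a fold change FC confined to a region that is
  fraction f of the sampled tissue appears whole-tissue as
  f·FC + (1 − f). With f = 1/10 and FC = 10 the observable effect is 1.9;
  with f = 1/30 it is 1.3 — the arithmetic case for profiling dissected
  tissue rather than whole heads.

## Antisense inference (`nat`)

Per query and reference species, the best hit's strand (min e-value, ties
as above) gives an orientation call; queries are classed sense-consistent,
antisense-consistent, discordant, or no-hit, with a high-confidence tier
for queries hitting **all** reference species, always antisense. An
all-hits mode judges consistency across every hit passing the cutoff
instead of the best hit only (config; the "one or more putative homologs"
phrasing supports either reading). Flipping every strand swaps the sense
and antisense classes and fixes discordant — a tested symmetry.

Sense/antisense pairs: each query is assigned to its single best subject,
and a subject matched by both a plus- and a minus-strand query yields the
pair (best plus, best minus), so a query joins at most one pair and the
result is row-order independent. Pair expression compares the mean probe
intensity of each member over a stage's arrays; a member missing
(flag 0) in ≥ 50% of those arrays excludes the pair. Filtering is applied
at the member level — the upstream description is ambiguous between
member- and pair-level filtering, and the member-level reading is flagged
here as our choice.

## Enrichment (`enrichment`)

One machinery, two styles: the GOStat-like route (min list count 3, plain
one-sided Fisher, raw p-values) and the DAVID-like route (min count 4,
EASE score = Fisher with one gene removed from the list-with-term cell,
BH-adjusted FDR reported as a percentage). The background is the custom
array background (annotated genes on the platform), never the genome, and
the gene list must be contained in it. EASE ≥ Fisher for every table
(property-tested), p-values match a brute-force hypergeometric tail sum on
all 2×2 tables with margins ≤ 30, and under a uniform random null the
Fisher p is super-uniform. GO ancestor propagation is available (and on
when a closure is supplied — historical tools differ here, so it is
config-exposed); closures can be derived from an OBO file via `obonet`.
The historical DAVID FDR column is not exactly recoverable; BH is used and
labeled. Any gene → label map (e.g. tissue annotations) runs through the
same functions.

## qPCR validation (`qpcr`)

Efficiency comes from the least-squares slope of Cp vs log10(input) over a
two-fold dilution series (≥ 3 distinct dilutions): E = 10^(−1/m), so a
perfect doubling assay (m = −3.3219) gives E = 2. Relative expression is
the efficiency-corrected (Pfaffl-form) calibrator-relative ratio
normalized to the reference gene; the Pfaffl form is preferred over
2^−ΔΔCp because per-assay efficiencies are measured. Duplicate Cp values
are averaged before the ratio (the combination rule is not documented
upstream). Reference-gene stability is CV% with sample (n−1) standard
deviation. Cross-platform agreement uses Spearman rank correlation with
average-rank ties, per probe and pooled. On noise-free synthetic data the
planted efficiencies and ratios are recovered exactly and the pooled rank
correlation is 1 (tested).

## Synthetic data (`simulate`)

The generator emulates the structure of the two-condition study — not
image-level or sequence-composition realism — with a single seed making
all outputs byte-identical:

* **Catalog:** `n_transcripts` random sequences of 200–3000 nt. Each
  planted antisense pair derives from a shared reference locus: the sense
  member copies a plus-strand subregion, the antisense member is the
  reverse complement of another, so hit tables show the two entries
  matching the same subject on opposite strands in every species.
* **Expression:** per-transcript log2 abundance ~ N(8, 1.5); both probes
  of a transcript share it plus a per-probe affinity offset (sd 0.3) and
  per-spot noise (sd 0.25). Planted DE transcripts are shifted in the
  deformed condition by magnitudes drawn from the default range
  0.16–3.97 log2 units — the fold-change span observed on the real
  platform (|FC| 1.12 to 15.7), down-regulated. The default design is two
  conditions × four replicate pools (the later-stage contrast). Ten
  spike-ins sit at fixed log2 levels 6–14 with sd 0.05, condition
  independent. Array distortions are affine on the log2 scale (hence
  monotone) so quantile normalization can remove them exactly. Flags are
  Bernoulli(1 − missingness) independent of condition (missingness is
  treated as technical) and forced to 0 below a detection floor (log2 = 2).
  The flag error behavior of real feature-extraction software is unknown,
  so missingness is a parameter, not a constant.
* **ESTs:** each transcript is tiled by overlapping reads (≥ 60 bp
  overlaps, 20% reverse-complemented) with known memberships.
* **qPCR:** Cp = intercept − log_E(quantity) + noise, duplicates
  everywhere, reference gene flat, dilution series of ≥ 5 two-fold steps;
  planted efficiencies are uniform in [1.8, 2.0].

What passing tests on this generator do **not** show: robustness to
spatial artifacts, non-monotone scanner effects, probe-sequence-dependent
intensity bias, condition-dependent missingness, or cross-hybridization —
none of which are simulated.

## Problem sizes

Simulation-based tests use catalogs of 30–500 transcripts, 4 + 4 arrays
(exhaustive 70-permutation SAM), 50-seed null batteries at 1000 probes,
and the full enumeration of 2×2 tables with margins ≤ 30 — sizes chosen so
each check is exact or well-powered while the whole suite stays fast. The
archived-series benchmark (`teleoarray.benchmark`) runs the same code on
the real platform's ~38k probes; it fetches the public series at run time
and therefore needs network access.

## Known limitations

* The consensus caller is not an assembler; indel-rich clusters will
  produce approximate consensi.
* Probe screens are transparent substitutes for a proprietary scorer;
  absolute probe sequences of the original platform are not reproduced.
* Absolute annotation counts from the original study depend on 2008-era
  databases and are out of scope; the machinery, thresholds and
  bookkeeping are what is reproduced.
* The DAVID-era FDR column and the GOStat default settings are
  approximated by BH and documented defaults.
* SAM q-values use a bounded delta grid on very large inputs (granularity,
  not correctness).
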