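# Methods

## Overview

`larpclip` analyses PAR-CLIP data in transcript space: every coordinate is
0-based half-open on a contiguous transcript partitioned into 5'UTR, CDS
and 3'UTR (one transcript per gene). The package has two halves — a
generative model that simulates a complete crosslinking study with known
truth, and the inference pipeline that is meant to recover that truth (and,
on real data, the biology): binding-site calling from T-to-C conversions,
expression normalization, regional/metagene localization, composition
statistics and enrichment analysis.

## The generative model (synthetic_data)

The simulator emulates a two-condition design in which an RNA-binding
protein relocates to pyrimidine-rich 5'UTR elements of
ribosomal-protein (RP) and other translation-related (TR) mRNAs when mTOR
is inhibited.

**Transcriptome.** `n_transcripts` (default 300) are drawn with region
lengths uniform on configurable ranges (5'UTR 60–200 nt, CDS 300–900 nt,
3'UTR 150–500 nt) over a uniform A/C/G/T background. Gene categories are
assigned by fraction (defaults 20% RP, 20% TR_other, rest non_TR; counts
are `round(n × fraction)`, Python ties-to-even). Planted features:

- RP transcripts start with a 5'TOP: cap-site C followed by `top_run_len`
  (default 5) pyrimidines.
- RP and TR_other transcripts carry a pyrimidine-enriched sequence (PES)
  footprint of `pes_len` (20 nt) ending exactly at the 5'UTR/CDS junction;
  each base is a pyrimidine with probability `pes_pyrimidine_rate`
  (default 0.9). These footprints emit reads only under `mTOR_off`.
- Every transcript carries one GA-rich 3'UTR footprint (25 nt; base
  probabilities A/G 0.4 each, C/T 0.1 each — guanine-rich but not T-free,
  so conversion evidence remains possible); non-TR transcripts additionally
  carry a purely positional CDS footprint. These are active in both
  conditions.

The design keeps TR_other transcripts PES-bearing but TOP-less: the 5'TOP
is the RP hallmark, while the condition-dependent 5'UTR relocation applies
to translation-related genes broadly. Footprint occupancy (expected reads
per footprint) defaults to 60 for 5'UTR PES footprints and 40 elsewhere.

**PAR-CLIP reads.** Per condition-active footprint, `Poisson(occupancy)`
reads of fixed length (30 nt, reflecting nuclease-trimmed fragments) are
placed with the read midpoint uniform over the footprint. Crosslink
positions are *all* reference Ts inside the footprint; each covered T reads
as C independently with `conversion_rate` (default 0.30). Background reads
(0.2 per kb) are uniform and conversion-free. Per-base sequencing errors
(rate 0.001) substitute a uniformly chosen different base. Multimapping is
created by copying a 40-nt cassette into the CDS start of 5% of non-TR
transcripts; any read falling entirely inside a copy is emitted once per
copy under the same read name.

**mRNA-seq.** Transcript abundances are log-normal (μ = 1, σ = 1,
normalized). Each replicate (default 2 × 500,000 reads) is an independent
multinomial draw with transcript probability ∝ abundance × available start
positions, then uniform placement; only sequencing errors apply. At this
depth replicate RPKM R² exceeds 0.99 by sampling theory, which the tests
verify.

**Determinism.** All randomness flows from `numpy.random.default_rng`
seeded with `[seed, stream, ...]` per stage/condition/replicate, so a
seed fixes every output byte.

**What the simulator does not model** — and hence what passing tests do
not certify about real data: realistic fragment-length and quality-score
distributions, PCR duplicates, ligation/RNase sequence bias, isoform
structure, genomic (spliced) alignment, and crosslink-position preference
within a footprint (real 4SU crosslinking favors particular Us; we spread
it over all footprint Ts to make conversion counting exactly testable).

## Site calling (sitecall)

Reads with more than 2 T-to-C mismatches are excluded (conversion evidence
beyond that is treated as noise), then single-linkage merged into clusters
by ≥ 1 nt overlap; half-open spans that merely touch do not merge. The
cluster's weighted coverage is convolved with a unit-mass Gaussian kernel
(σ = 5 nt, truncated at 4σ, computed on a 4σ zero-pad so pre-trim mass is
conserved exactly); boundaries are the contiguous run of smoothed coverage
≥ 0.5 containing the maximum, clipped to the transcript. σ = 0 degenerates
to a delta kernel (raw spans). Clusters are retained as binding sites iff
they contain ≥ 1 conversion-bearing read and pass the RPM threshold; the
threshold is an explicit parameter (default 1.0 RPM) with
`suggest_rpm_threshold` locating the knee of the RPM curve for data-driven
choice. The RPM filter is applied before expression normalization. Sites
on transcripts with zero or missing RPKM are kept with the normalized
score marked undefined rather than dropped.

Consequence worth knowing: on pyrimidine-rich footprints at conversion
rate 0.3, a substantial share of footprint reads carries > 2 conversions
and is filtered, so observed 5'UTR coverage sits below the raw occupancy
share. The truth-table expectation (`expected_region_fractions`) therefore
folds the same ≤ 2-conversion retention probability (a binomial CDF over
covered Ts, averaged over read midpoints) into the expected coverage — an
oracle computed from the generative model alone, never from reads.

## Expression (expression)

Only perfect-match, forward, ungapped reads count; a read with k perfect
placements contributes 1/k per placement, and the library total is the sum
of those weights. RPKM uses the standard definition; replicate RPKMs are
arithmetically averaged and a gene is "expressed" with > 0 counted reads in
≥ 1 replicate (this defines the enrichment background). Pearson r/R² is
reported per replicate pair; undefined correlations (zero variance) are
reported as NaN and averaging proceeds.

## Annotation and metagene (annotate_metagene)

A site's region is the one holding the largest share of its span, ties
broken 5'UTR > CDS > 3'UTR. Coverage currency is the expression-normalized
score, falling back to RPM (flagged) when normalization is undefined.
Metagene profiles scale each transcript to [0,1] as a whole — regions are
not separately rescaled — with the mean fractional junction positions drawn
as boundary marks; site coverage is spread over bins proportionally to
overlap, so bin mass conservation is exact. Note the aggregate coverage
percentages are expression-weighted (1/RPKM), so low-abundance transcripts
carry large weights and the category percentages fluctuate more than raw
read fractions.

## Sequence statistics (seqstats)

Welch's two-tailed t-test is computed from the closed-form statistic and
Welch–Satterthwaite degrees of freedom; zero variance in both groups is
degenerate (p = 1 with equal means, else p = 0, logged). Bound-vs-unbound
composition compares, per transcript with a bound segment in scope, the
bound union against the remainder of the same region (pyrimidine fraction
for 5'UTRs, G fraction for 3'UTRs), as an *unpaired* two-sample test; a
paired variant would gain power but the unpaired form matches the reported
design, and per-region-per-transcript values (not pooled nucleotides) are
the unit of analysis. Motif discovery is deliberately out of scope: the
stand-ins are the longest pyrimidine run over sites extended ±15 nt
(summarized as the fraction with run ≥ 6) and an enriched-hexamer count
against composition-preserving shuffles, plus a FASTA export of extended
site sequences for external motif finders. The 5'TOP call — cap C followed
by ≥ 4 pyrimidines, configurable — is an operational definition chosen
here (no universal one exists) and is echoed in output headers.

## Enrichment (enrichment)

Classic per-term one-sided Fisher exact tests (no graph decorrelation),
Bonferroni-corrected over the terms tested, significant at adjusted
p < 0.001. The background is the expressed-gene set. Annotation may carry
parent links for upward propagation; otherwise it is flat. Significant
terms are grouped by a manually curated term → super-category table (a
small default covering the translation super-category ships with the
package); a gene is translation-related iff annotated to ≥ 1 translation
term. TE classes: fold change < 1/1.5 "down", > 1.5 "up", else
"unchanged". On default synthetic data every gene carries 3'UTR binding,
so "any bound gene" equals the background and per-term enrichment is
uninformative by construction; the selective set is genes gaining 5'UTR
sites under mTOR inhibition, which the acceptance script uses for its
enrichment and TE measurements.

## Pipeline (pipeline, cli)

Stages run in a fixed order (simulate/load → quantify → call → annotate →
sequence stats → enrich) under a single YAML config plus CLI overrides; a
failure aborts naming the stage and preserves earlier outputs. The manifest
records the seed, caller parameters, replicate concordance and SHA-256
checksums of every output; determinism is asserted by comparing manifests
of repeated runs. The default problem size (300 transcripts, 2 × 500k-read
replicates per condition) keeps a full two-condition run under a minute on
one CPU while leaving thousands of footprint reads per category.

## Numerical and edge-case choices

- Half-open interval convention everywhere internally; SAM written 1-based.
- N bases: excluded from composition denominators, never counted as
  mismatches or conversions.
- Mismatches are recovered by comparing read to reference (no MD/NM trust).
- Reverse-strand and gapped records are rejected with warnings
  (sense-strand, ungapped libraries assumed).
- Best-stratum placement reports all tied placements in (transcript,
  position) order, truncated to `max_hits`; ordering of ties is positional
  by construction.
- Empty inputs: empty read sets yield empty cluster/site lists; a category
  with no sites yields an all-zero metagene; an empty truth table yields a
  header-only SAM.

## Known limitations

- Transcript space only: no exon-aware genomic metagenes, no isoforms.
- No crosslink-nucleotide-resolution boundaries (kernel-density
  classification à la PARalyzer) and no replicate-aware site
  reproducibility scoring.
- The exhaustive placer is for desk-scale validation, not a production
  aligner.
- The enrichment module is not a full GO reasoner: no OBO parsing or
  semantic-similarity clustering; super-categories come from the curated
  mapping file.
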