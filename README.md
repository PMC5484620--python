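# larpclip

Transcriptome-space PAR-CLIP analysis for RNA-binding-protein relocation
studies, built around the LARP1/mTOR experimental design: call protein
binding sites from T-to-C conversion-bearing reads, quantify transcript
expression from replicate mRNA-seq, localize binding to 5'UTR/CDS/3'UTR,
profile it along normalized transcript length, test the pyrimidine/guanine
composition of bound regions, and measure GO-term and translation-efficiency
enrichment of bound genes. A ground-truth simulator generates complete
synthetic studies (transcriptome, PAR-CLIP and mRNA-seq libraries), so every
stage is exercisable and testable without any external data.

## Who this is for

Computational biologists analyzing PAR-CLIP (or similar crosslink-conversion
CLIP) data against a transcriptome, and method developers who need a
simulator with planted footprints and known conversion rates to validate a
site caller end to end.

## The model

PAR-CLIP reads originating from a crosslinked protein footprint carry
characteristic T-to-C conversions. The caller mirrors the classic
transcriptome-space recipe:

1. **Mapping policy** — ungapped placements with ≤ 3 mismatches, best
   stratum only, ≤ 100 hits; a read mapping to *k* positions gets weight
   1/*k* at each (even multimapper distribution).
2. **Clustering** — reads with 0–2 T-to-C mismatches are merged into peaks
   by ≥ 1 nt overlap (half-open coordinates).
3. **Smoothing** — weighted per-base coverage is convolved with a Gaussian
   kernel (σ = 5 nt, truncated at 4σ) and the span trimmed to the
   contiguous run ≥ 0.5 coverage containing the maximum.
4. **Filtering & scoring** — clusters with ≥ 1 conversion-bearing read and
   RPM ≥ threshold become binding sites, where
   `RPM = Σ member weights / (mapped reads / 10⁶)` and the
   expression-normalized score is `RPM / gene RPKM × 1000` with
   `RPKM = (count / (total/10⁶)) / (length/10³)`.

Downstream statistics: Welch's two-tailed *t*-test for bound-vs-unbound
composition (pyrimidine fraction in 5'UTRs, G fraction in 3'UTRs),
longest-pyrimidine-run and enriched-hexamer motif summaries over ±15 nt
extended sites, 5'TOP classification (cap C + pyrimidine run), one-sided
Fisher exact GO enrichment with Bonferroni correction (significant at
adjusted p < 0.001) grouped into super-categories, and a cross-tabulation
of bound genes against >1.5-fold translation-efficiency changes.

## Worked example

Run the full synthetic study (300 transcripts, 20% ribosomal-protein (RP)
genes, paired mTOR-on/mTOR-off PAR-CLIP libraries, two mRNA-seq replicates
per condition) and inspect the condition-dependent relocation:

```sh
larpclip run-all --seed 7 --outdir run7 --condition both
```

```
run complete: run7/manifest.json
```

The run directory contains the simulated FASTA/GFF/SAM inputs, the truth
tables, and every analysis table. The region-coverage table
(`run7/region_coverage.tsv`) shows the headline pattern — RP 5'UTR binding
appears only when mTOR is inhibited:

```
category  region  condition  coverage    pct
RP        UTR5    mTOR_off   48501.5     48.6561
RP        UTR5    mTOR_on    0.0         0.0
RP        UTR3    mTOR_off   51180.6     51.3439
non_TR    UTR5    mTOR_off   0.0         0.0
...
```

`pct` is the share of expression-normalized binding coverage a region
receives within its gene category and condition. The composition tests
(`run7/composition_tests.tsv`) report, for example, that bound 5'UTR
segments are far more pyrimidine-rich than the unbound remainder of the
same 5'UTRs (Welch *t* = 20.3, p = 5.5e-53 on these simulated data), and
`run7/manifest.json` records replicate mRNA-seq RPKM concordance
(R² ≈ 0.9992 at 500k reads/replicate) plus a SHA-256 checksum of every
output, so rerunning with the same seed is verifiably byte-identical.

Library use mirrors the CLI:

```python
from larpclip import SimulationSpec, generate_transcriptome, simulate_parclip

spec = SimulationSpec(n_transcripts=100, seed=1)
transcripts, truth = generate_transcriptome(spec)
reads = simulate_parclip(transcripts, truth, spec)
```

## Layout

- `src/larpclip/synthetic_data.py` — simulator and truth-based evaluation
- `src/larpclip/alignment_io.py` — SAM/BED I/O, conversion counting,
  multimapper weights, exhaustive best-stratum placer
- `src/larpclip/expression.py` — RPKM, replicate averaging, concordance
- `src/larpclip/sitecall.py` — clustering, smoothing, filtering, scoring
- `src/larpclip/annotate_metagene.py` — region assignment, coverage tables,
  metagene profiles
- `src/larpclip/seqstats.py` — composition tests, motif runs, 5'TOP
- `src/larpclip/enrichment.py` — GO Fisher enrichment, super-categories, TE
- `src/larpclip/pipeline.py`, `src/larpclip/cli.py` — orchestration and CLI

See `docs/methods.md` for the modeling choices and their rationale.
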