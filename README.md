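# regenomics

Differential multi-omic analysis of bisection-injury regeneration time
courses, built as a reusable, tested pipeline. It covers the statistical
core of a head/foot regeneration study design — a 2 structure x 4 timepoint
(0/3/8/12 hpa) x 2 treatment (untreated / TCF-inhibitor) factorial with
matched RNA and chromatin-accessibility count data:

- **`regenomics.synthio`** — synthetic experiment generator: NB counts on a
  toy genome with a generic 3-hpa injury program, structure-specific
  programs from 8 hpa, an inhibitor arm with delayed divergence, motif
  placements tied to the planted programs, scored peak replicate lists, TSS
  coverage profiles, and a two-cluster single-cell matrix; all outputs are
  a pure function of (config, seed) and ship with machine-readable truth.
- **`regenomics.formats`** — TSV count matrices + sample sheets,
  narrowPeak/BED6 (0-based half-open), JASPAR-like PWM text, FASTA,
  JSON/YAML. Every writer/reader pair round-trips exactly.
- **`regenomics.diffexpr`** — CPM filtering, TMM normalization, NB log-link
  GLMs with empirical-Bayes-shrunk dispersions, quasi-likelihood F-tests
  with moderated quasi-dispersions, BH adjustment, head-vs-foot context
  effects (difference-of-differences contrasts), TCF-dependent/-inhibited
  classification, and Wilcoxon rank-sum structural enrichment for
  single-cell clusters.
- **`regenomics.consensus`** — rank-based Gaussian copula mixture IDR
  (EM with model-consistent pseudo-values), the reproducible-peak consensus
  rule (global IDR <= 0.1 in >= 3 pairwise replicate comparisons in >= 1
  group), binomial pseudo-replicate splitting, self-consistency / rescue
  ratios, and the aggregate TSS enrichment score.
- **`regenomics.motifs`** — both-strand PWM log-odds scanning, 250-bp
  fixed-width peak recentering, bias-corrected motif deviation z-scores
  against GC/abundance-matched background peaks, per-timepoint deviation
  significance, and motif-redundancy clustering with max-variability
  representatives.
- **`regenomics.enrich`** — exact hypergeometric enrichment, peak-to-gene
  assignment (gene-body overlap, else nearest start within 20 kb),
  peak/gene concordance, Fisher motif enrichment, and the four-criteria
  candidate-TF screen (accessibility up + TF up + motif enriched + site
  near a listed gene).
- **`regenomics.cli`** — stage orchestration.

## CLI

```sh
regenomics run --outdir myrun --seed 3            # full chain
regenomics simulate --outdir myrun --seed 3       # individual stages:
regenomics qc --outdir myrun
regenomics differential --outdir myrun
regenomics deviations --outdir myrun
regenomics concordance --outdir myrun
regenomics screen --outdir myrun
regenomics report --outdir myrun
```

Stages communicate through plain-text files in the workspace directory and
are deterministic for a fixed config + seed (reruns are byte-identical).
Key thresholds are exposed both in YAML config and as flags: `--fdr-rna`
(default 1e-3), `--fdr-atac` (1e-4), `--idr-cut` (0.1), `--min-pairs` (3),
`--peak-width` (250), `--max-gene-distance` (20000). Unknown config keys
are rejected. `report.md` summarizes QC, significant context features per
timepoint, and screen candidates.

## Conventions

- Genomic coordinates are 0-based, half-open everywhere.
- Statistical contract: the differential engine follows the NB
  quasi-likelihood model family; it is validated by calibration and
  recovery properties rather than numerical identity with any particular
  reference implementation.
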