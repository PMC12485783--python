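# allergome

A tested, reusable pipeline for the computational core of a multi-omics
(DNA / RNA / methylome) mouse study of allergen-driven lung cancer,
exercised end-to-end on a synthetic benchmark with known planted truth:

- **variant_consensus** — ensemble consensus of four somatic callers
  (retain variants called by ≥ 2 callers) plus post-calling filters:
  known-SNP blacklist, matched-germline subtraction, shared-across-samples
  exclusion, and clustered-mutation exclusion (> 3 mutations within a
  10 bp window). Filters flag rather than delete, so
  `|input| = |retained| + |flagged|` always holds.
- **mutation_spectra** — SBS96 / DBS78 / ID83 channel classification from
  the reference sequence (COSMIC v3 label conventions), per-Mb mutational
  burden, profile averaging, and cosine-similarity comparison.
- **expression_stats** — row-sum count filter, median-of-ratios size
  factors, TPM and log2(TPM+1), TMM-normalized log2 CPM (validated against
  edgeR), a lightweight NB-Wald differential-expression test with
  median-shrunk method-of-moments dispersions, BH-FDR, and DEG calling at
  |log2FC| ≥ 1 and FDR < 0.05.
- **module_scoring** — per-gene z-scores, gene-set mean-z module scores,
  marker-mean signature scores for cell populations (marker sets are
  pluggable GMT inputs), exact Wilcoxon rank-sum and Welch comparisons
  with BH across populations.
- **methylation_analysis** — beta/M-value handling, differential
  methylation at |Δβ| ≥ 0.2 and p < 0.05 (Welch t on M-values),
  aggregation to tiling / gene / promoter / CpG-island features, region
  log2 quotients (`mean_quot_log2`), hyper/hypo counting.
- **omics_integration** — promoter-methylation ↔ expression pairing,
  five-category effect-size quadrants (cuts 1.0 expression / 0.1
  methylation), and the inverse-correlation filter defining epigenetically
  controlled genes (DEG ∩ DMG with opposite directions, Pearson r ≤ −0.6,
  p < 0.1).
- **synthetic_data** — deterministic generator for the reference contig,
  per-sample per-caller VCF call sets (with planted blacklist, germline,
  shared and clustered contaminants), negative-binomial counts with
  planted DEGs, logit-normal beta values with planted DMSs, and 12 + 8
  genes with inversely coupled promoter methylation and expression. Every
  planted item is recorded in machine-readable truth tables.
- **pipeline_cli** — one-config orchestration of all stages with
  file-on-disk handoff, run reports, and config validation.

## CLI

```sh
# full synthetic end-to-end run (simulate -> consensus -> spectra ->
# expr -> methyl -> score -> integrate), outputs under out/
allergome run --outdir out --seed 42

# generate only the synthetic inputs (FASTA, VCFs, TSV matrices, truth)
allergome simulate --outdir sim --seed 42

# check a YAML config without running anything
allergome validate --config cfg.yaml
```

The YAML config has two sections: `synthetic` (generator sizes, effect
sizes, seed — see `SyntheticConfig`) and `thresholds` (every analysis
cutoff; defaults reproduce the study settings: min_callers 2, cluster
window 10 bp / > 3, |log2FC| ≥ 1 & FDR < 0.05, |Δβ| ≥ 0.2 & p < 0.05,
r ≤ −0.6 & p < 0.1, quadrant cuts 1 and 0.1).

## Notes

- Coordinates are 1-based inclusive in variant handling (VCF convention);
  BED-like interfaces are 0-based half-open.
- The consensus VCF reader is deliberately strict (the htslib-based
  readers silently coerce malformed records; this one raises with the
  offending line number) and handles the five mandatory columns with
  multi-allelic splitting.
- `tests/` contains brute-force oracles for every classifier and filter;
  `tests/test_acceptance.py` mirrors the acceptance criteria one test per
  criterion.
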