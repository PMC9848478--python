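# epistate

Spike-in-normalized chromatin-state analysis of promoters and transposable
elements (TEs), packaged as a reusable library plus a small stage-oriented
pipeline. The package covers:

- **regionio** — genomic region model (0-based half-open), strand-aware
  promoter windows from TSSs (default −2000/+500 bp), BED / region-table /
  ENCODE broadPeak–narrowPeak readers and writers.
- **spikenorm** — per-antibody spike-in normalization factors (geometric-mean
  reference), input/length/spike-normalized signal matrices, and sliding
  window / genome-bin profiles.
- **peakrep** — pseudoreplicate splitting, a minimal Poisson window peak
  caller for synthetic data, the replicate/pseudoreplicate retention rule,
  and FDR filtering (histone q < 1e-3, ATAC q < 1e-4).
- **chromstate** — binary occupancy calls (peak overlap AND signal above the
  negative-region mean), combinatorial repressive/active/bivalent/neutral
  state assignment, cell-type specificity, signature transition tables, and
  TE-family enrichment.
- **exprmeth** — log2(RPKM+1) quantification against protein-coding-mapped
  totals, expression categories (TE: ≤0.4 / ≤1.4; gene: ≤1.5 / ≤5.0), the
  ≥4-fold DE rule with the 0.4 floor, and region methylation means over
  CpGs covered >5×.
- **telink** — nearest-TSS TE-gene assignment (<100 kb), distance-binned
  TE–gene differential-expression correlation, regulatory-TE classification.
- **somgrid** — from-scratch online self-organizing map on a 10×10 toroidal
  grid (rlen=5000, alpha 0.09→0.01) with feature preparation (log2
  transform + z-scaling; methylation scaled only).
- **effstats** — Wilcoxon rank effect size r = |Z|/√N, chi-square
  goodness-of-fit effect size (Cohen's w), Pearson r, and the
  n / * / ** / *** effect-size levels (0.2 / 0.3 / 0.5).
- **synthgen** — ground-truth synthetic data generator: NB IP/input counts
  with a constant spike admixture, mark × cell-type abundance multipliers,
  persistent cross-cell mark states, state-coupled bimodal expression with
  planted DE and correlated TE–gene deltas, and binomial CpG methylation.
- **pipeline / cli** — YAML-configured stage orchestration with content-hash
  manifests and idempotent reruns.

## CLI

Stages read a single YAML config and run in dependency order:

```yaml
# cfg.yaml
outdir: out/
seed: 1
synthetic: {n_promoters: 120, n_tes: 240}
som: {rlen: 5000}
```

```sh
epistate all --config cfg.yaml            # simulate -> ... -> report.json
epistate simulate --config cfg.yaml       # single stage (use --force to redo)
epistate peaks-retain --pooled pooled.broadPeak --rep1 r1.broadPeak \
    --rep2 r2.broadPeak --psr1 p1.broadPeak --psr2 p2.broadPeak --out kept.broadPeak
epistate peaks-filter --peaks kept.broadPeak --assay histone --out final.broadPeak
```

Stage outputs, parameters, the seed, and sha256 hashes of every file are
recorded in `out/manifest.json`; re-running an up-to-date stage is a no-op.

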