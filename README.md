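# breakdomains

Calling and quantifying γH2AX spreading domains around site-specific DNA
double-strand breaks (DSBs) on tiling-array ChIP signals.

When a DSB is induced at a defined genomic site, the histone variant
H2AX is phosphorylated (γH2AX) over megabase-scale chromatin domains
flanking the break.  The spreading is uneven: inside a domain, "holes"
of depleted γH2AX coincide with narrow cohesin peaks and active genes,
and depleting cohesin raises γH2AX in *cis* on exactly those regions.
This package implements the desk side of that analysis for probe-level
tiling-array data (one value per ~35 bp probe):

* **Signal processing** — bedGraph/refFlat I/O, cross-array quantile
  normalization to a target scale, log2 IP/input ratios, probe-count
  and bp sliding-window smoothing (`breakdomains.tracks`,
  `breakdomains.formats`).
* **Seed-and-extend zone caller** — enriched zones of any size are
  seeded as windows of *N* consecutive probes with at least *m* probes
  strictly above a per-chromosome nearest-rank percentile threshold
  *T*, refined by probe-wise bidirectional edge extension, then merged
  and filtered on size and score.  The same machinery calls broad
  γH2AX domains, narrow cohesin peaks (the 20-probe / ≥17-above /
  90th-percentile setting), and depleted holes (the caller applied to
  the negated in-domain signal) (`breakdomains.caller`).
* **Metaprofiles** — break-site-centered, strand-oriented TSS, and
  boundary-overlaid average profiles with left/right mirroring, plus
  Hi-C contact-matrix pileups around domain boundaries
  (`breakdomains.profiles`).
* **Break statistics** — windowed means at sites, paired *t*-tests
  between conditions, a uniform random-site permutation null,
  per-gene signal summaries, Pearson correlation of cohesin occupancy
  against the γH2AX depletion ratio, stratified comparisons, and
  one-sample expression-ratio tests (`breakdomains.stats`).
* **Synthetic data with ground truth** — a seeded generator that
  emulates the study conditions (two tiled chromosomes, 24 cleaved
  sites, tapered megabase domains with holes, TSS-biased cohesin
  peaks, a local post-induction cohesin bump, Gaussian log2 noise, and
  an in-*cis* depletion effect), so the whole pipeline is testable
  without array downloads (`breakdomains.simulate`).

## Worked example

```python
from breakdomains import (SynthConfig, simulate_fixture, call_enriched_domains,
                          call_holes, PRESETS, paired_site_test, genes_in_domains,
                          gene_signal, signal_ratio_correlation)

cfg = SynthConfig(seed=7)                      # 24 DSBs on 60 + 40 Mb chromosomes
genome, truth, tracks = simulate_fixture(cfg)
gx = tracks["gH2AX_ctrl_p4OHT"]                # post-induction gamma-H2AX, control

domains = call_enriched_domains(gx, PRESETS["gammaH2AX_domains"])
holes = call_holes(gx, domains, PRESETS["holes"])

res = paired_site_test(tracks["cohesin_m4OHT"], tracks["cohesin_p4OHT"],
                       truth.dsb_sites, window_bp=2000)

genes = genes_in_domains(truth.genes, truth.true_domains, mode="contain")
coh = gene_signal(tracks["cohesin_m4OHT"], genes)
ratio = (gene_signal(tracks["gH2AX_depl_p4OHT"], genes)
         - gene_signal(tracks["gH2AX_ctrl_p4OHT"], genes))
r, p, n = signal_ratio_correlation(coh.to_numpy(), ratio.to_numpy())
```

prints (via the obvious `print` statements):

```
called 24 spreading domains (median width 589,996 bp) and 77 holes
cohesin at breaks, +/-1 kb window: mean log2 increase 0.388 (paired t = 41.48, df = 23, p = 3.99e-23)
per-gene cohesin vs gamma-H2AX depletion ratio: r = 0.50 (p = 8.8e-07, n = 87 in-domain genes)
```

All 24 implanted domains are recovered; the paired test at the 24 break
sites detects the weak (~0.4 log2) local cohesin increase after break
induction; and the per-gene correlation shows that the γH2AX gain upon
cohesin depletion falls preferentially on cohesin-bound genes — the
in-*cis* effect the pipeline is built to measure.

A `breakdomains` console script exposes the same stages
(`simulate`, `normalize`, `ratio`, `smooth`, `call`, `profile`,
`stats`); see `breakdomains --help`.

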