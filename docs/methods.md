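# Methods

This note documents the models, conventions and design choices behind
`breakdomains`: what the synthetic generator emulates, how the
seed-and-extend caller is defined, the averaging and testing
conventions, and the known limitations of each.

## Coordinates and signal carrier

All coordinates are 0-based, half-open `[start, end)`.  A probe is a
point at the start of its 1-bp bedGraph interval; a `ProbeTrack` holds,
per chromosome, strictly increasing probe positions and one finite
value per probe (raw intensity or log2 IP/input ratio).  Missing probes
are absent rather than NaN, so every downstream mean is over observed
probes only.

## Array preprocessing

**Quantile normalization.**  Arrays of equal length are mapped onto the
across-array mean of per-rank sorted values; tied input values receive
the mean of the reference values their tie run spans.  The target
"scale" is interpreted as the post-normalization per-array mean: after
the quantile step each array is rescaled multiplicatively so its mean
equals `scale` (500 by default, matching the conventional tiling-array
setting).  If the reference mean is non-positive, an additive shift is
used instead so rank order is never inverted.  The mean-target reading
is a choice — a trimmed mean or median target would also be defensible —
and is therefore explicit in the API rather than hidden.

**Smoothing.**  Two modes: a centered moving mean over probe *indices*
(window in probes; edges shrink the window; even windows are promoted
to the next odd size so centering is unambiguous) and a moving mean
over *positions* (window in bp, half-open on the right:
`[pos − w/2, pos + w/2)`).  Probe-count windows reproduce wide
chromosome views (e.g. 500-probe smoothing); bp windows are used for
anchor-relative averaging (200 bp around hole borders and TSSs, 10 kb
around domain boundaries).

## The seed-and-extend caller

The caller detects enriched zones of any size in two steps, with a
merge/filter stage after them.

1. **Threshold.**  `T` is the nearest-rank percentile (sorted value at
   1-based rank `ceil(pct/100·n)`, no interpolation) of the
   chromosome's values, computed per chromosome.  "Above threshold" is
   strict (`>`).
2. **Seeding.**  Every window of `n_seed` consecutive probes with at
   least `min_above` probes above `T` qualifies; the union of
   qualifying windows, split into maximal runs, gives candidate zones.
   Note the union overreaches a sharp enrichment edge by up to
   `n_seed − min_above` probes per side; with 35 bp spacing and the
   default 50/40 setting that is ≤ 350 bp, far below the kb-scale
   accuracy the pipeline needs.
3. **Extension.**  Each candidate edge advances one probe at a time
   while the `ext_window` probes ending at the tentative new edge
   (looking back into the zone) contain strictly more than
   `ext_fraction · ext_window` probes above `T`; the first failure
   stops that side.  The left edge is refined before the right, and
   extension never crosses a chromosome end or a neighbouring seed.
   Defaults: `ext_window = n_seed`, `ext_fraction = min_above/n_seed`.
   The published description states the principle (bidirectional
   refinement by percent-above-threshold) but not the stopping rule;
   this edge-window rule is one faithful, fully specified reading, and
   both knobs are configurable.
4. **Merge/filter.**  Same-chromosome zones whose gap is below
   `merge_gap_bp` are coalesced (strictly overlapping zones always
   are); scores are then recomputed over every probe in the merged
   span.  Zones are kept only if they meet all of `min_probes`,
   `min_bp` and `min_mean_score`.

**Presets.**  `cohesin_peaks` uses the published setting — 20-probe
seeds, ≥ 17 above, 90th percentile — with permissive merge/filter
values.  The `gammaH2AX_domains` preset (50-probe seeds, ≥ 40 above,
70th percentile, 30 kb merge gap, ≥ 50 kb) and the `holes` preset
(20/14, 90th percentile of the *negated in-domain* values, 1 kb gap,
≥ 2 kb) are this package's defaults; the corresponding published runs
never state their numbers.  The rationale: the percentile must sit in
the background bulk, so with ~15% of probes inside domains the 70th
percentile is safely below the enriched mass while the 85th–90th would
not be; the 30 kb merge gap must exceed the widest expected hole
cluster (holes are internal domain structure, not domain breaks) while
staying far below the Mb-scale gaps between domains.

**Hole calling** runs the same caller on the negated signal restricted
to the probes of previously called domains, with the threshold taken on
the pooled negated in-domain values of the chromosome; extension is
confined to the parent domain, so holes are contained by construction.
The reported `mean_score` of a hole is its mean depletion depth
(negated signal).

An exhaustive, loop-based reference implementation of the entire caller
lives in `breakdomains.reference`; the test suite and the acceptance
script verify exact agreement with the vectorized caller on ~1,000
random track/parameter combinations.

## Metaprofiles

Profiles pool all (anchor, probe) pairs whose offset falls in each bin
— they are **pair-pooled**, not per-anchor-averaged.  This makes the
profile of a union of anchor sets the pair-count-weighted mean of the
per-set profiles and is robust to anchors with missing probes; when
coverage is even the two conventions coincide.  Offset bins are
half-open `[k·w, (k+1)·w)`; offset 0 falls in the first non-negative
bin, so the bin straddling the anchor is intentionally "mixed" at sharp
steps.  Reported offsets are bin centers; each bin carries both the
pair count `n` and the number of distinct contributing anchors.

Mirroring: boundary overlays keep right borders as-is
(offset = pos − boundary) and mirror left borders
(offset = boundary − pos), so negative offsets always point into the
zone.  TSS profiles negate offsets of minus-strand genes so positive
offsets always point in the direction of transcription.  Anchors near
chromosome ends contribute partial windows rather than being dropped.

Hi-C boundary pileups average square submatrices centered on each
boundary's bin, flipping right-boundary submatrices along both axes;
after mirroring the domain interior lies on the positive-offset side.
Boundaries whose window would cross the matrix edge are skipped (and
counted); matrices are used as given — no ICE/KR balancing, loop
calling or compartment analysis is attempted.

## Statistics

* Window membership at sites is closed: `|pos − site| ≤ window/2`.
  Strand-oriented TSS windows are half-open `[lo, hi)` in oriented
  offset coordinates.
* The paired *t*-test uses per-site (or per-gene) window means, pairs
  matched by identity, two-sided *p*, `df = n − 1`.  A design whose
  differences are all exactly zero reports `p = 1` (the null is
  literally exact); a zero-variance design with a nonzero mean raises
  a degenerate-test error rather than returning an unstable number.
* The random-site null draws `sites_per_set` positions uniformly
  (chromosomes weighted by length), repeats the paired test `n_sets`
  times, and reports the per-set *p*-values, the fraction below α and
  the quartiles of log10 *p* — all reproducible from one seed.
* Pearson correlation uses the *t*-transform *p* with `df = n − 2`,
  two-sided (sidedness is a convention here; the source analyses do
  not state theirs).  NaN pairs are dropped.
* The stratified comparison uses Welch's two-sample *t*-test between
  the low- and high-ratio gene groups.
* Expression changes are tested per gene by a one-sample *t* of
  replicate fold changes against the no-change ratio of 1.
* No multiple-testing correction is applied anywhere; the pipeline
  reports raw per-test *p*-values (with the number of tests available
  to the caller), matching the source analyses.

## The synthetic generator

The generator's defaults encode the study conditions at desk scale:
two chromosomes (60 Mb + 40 Mb) stand in for the two tiled human
chromosomes, with a 35 bp probe grid; 24 break sites carry enrichment
domains of ~0.3 Mb halfwidth (clipped normal), keeping the fraction of
probes inside domains (~15%) close to the real design — the quantity a
percentile-threshold caller is actually sensitive to.  600 genes match
the real per-Mb gene density of the tiled chromosomes; the number that
end up inside domains (~80–90) is proportionally consistent with the
megabase-domain geometry.  Features:

* **Domains** are rectangular plateaus (1.0 log2 by default) with a
  linear edge taper of 10% of the halfwidth.  The true decay shape at
  domain edges is unknown; a plateau with taper was chosen because it
  gives unambiguous ground-truth boundaries for recovery scoring.
* **Holes** (3 per domain, 8 kb, full-depth) are centred on cohesin
  peaks inside the domain when available, otherwise placed uniformly
  in the interior; they keep one hole-width clear of the domain edges
  so the true boundary remains identifiable, and overlapping holes are
  merged in the truth set.
* **Cohesin peaks** (300 × 1 kb, 1.5 log2) are centred within ±0.5 kb
  of a TSS for a configurable fraction (default 0.7) of peaks,
  mirroring promoter-biased cohesin occupancy.
* **Break-local cohesin** is a triangular bump (±2.5 kb, 0.5 log2 at
  the apex) present only in the post-induction cohesin track —
  the weak, confined recruitment signature.
* **Depletion effect**: the cohesin-depleted post-induction γH2AX
  track gains +0.4 log2 on probes inside cohesin peaks and nowhere
  else, encoding the in-*cis* claim exactly; with the effect set to 0
  the gene-level correlation is statistically indistinguishable from
  zero.
* **Noise** is i.i.d. Gaussian (0.3 log2 sd by default) per probe and
  track.  Break sites are placed one per equal-width chromosome slot
  (jittered), which guarantees non-overlapping domains and end
  margins; an infeasible packing raises an error naming the
  constraint.

All randomness flows from a single `numpy` generator seeded by the
config (noise is drawn in a fixed track/chromosome order so fixtures
are identical regardless of which track subset is requested); identical
(config, seed) pairs produce byte-identical fixtures on disk.

The contact-matrix simulator is deliberately minimal: bins sharing a
truth domain interact at a high mean, all other pairs at background,
with optional symmetric Gaussian noise — just enough structure for the
boundary-pileup operation to have a sharp expected answer.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real arrays: probe-specific affinity and GC
effects, replicate/batch structure, heavy-tailed or spatially
correlated noise, copy-number variation, partial cleavage of break
sites, distance-decay in contact matrices, and genuine transcriptional
readouts (expression fold changes are exercised on constructed
replicate tables, not simulated biology).

## Problem sizes and numerics

The test suite and the acceptance script run the recovery analyses on
the full-size default fixtures (≈ 2.9 M probes per track) over 10–20
seeds, the caller-vs-reference comparison on 300–1,000 random tracks of
≤ 500 probes, and the null calibration on 1,000 site sets; the whole
suite completes in well under two minutes per stage on one CPU.  Exact
contracts (caller equivalence, quantile sorted-column identity, pileup
quadrant means) are asserted exactly or at 1e-9–1e-12; statistical
recoveries use tolerances derived from their sampling distributions
(e.g. ±0.08 on r at n = 359, the binomial band [0.03, 0.07] for a 5%
null rate over 1,000 sets).

## Known limitations

* The caller is threshold-based; enrichment below the percentile
  threshold or domains occupying most of a chromosome (pushing the
  percentile into the enriched mass) are out of its operating range —
  choose `threshold_percentile` below the background fraction.
* Hole calling inherits domain-edge tapers: a decaying edge inside a
  called domain can be flagged as depleted. This affects precision at
  edges, not the recovery of implanted holes.
* `mean_score` of merged zones is recomputed over the whole merged
  span (including bridged gaps) when the track is available, which is
  the natural definition but differs from a member-only average.
* Per-gene summaries treat a gene as its `[txStart, txEnd)` span; no
  isoform or exon structure is modelled.
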