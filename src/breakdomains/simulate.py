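"""Synthetic tiling-array ChIP fixtures with known ground truth.

The generator emulates the statistical structure of ChIP-chip data
around sequence-specific double-strand breaks on a two-chromosome
tiling design (~35 bp probe spacing):

* megabase-scale gamma-H2AX enrichment plateaus centred on each break
  site, with an optional linear taper at the edges and internal
  depleted "holes";
* narrow cohesin peaks, a configurable fraction of them centred within
  1 kb of a TSS (cohesin accumulates at promoters);
* a weak, local (few-kb) cohesin increase at break sites present only
  after break induction;
* a paired condition pair (control vs cohesin-depleted) in which the
  post-induction gamma-H2AX signal is elevated *in cis* on
  cohesin-bound probes only;
* i.i.d. Gaussian log2-ratio noise on every track.

Every draw flows from one seeded :func:`numpy.random.default_rng`
generator, so a (config, seed) pair reproduces fixtures byte-for-byte.
With ``noise_sd = 0`` every probe value is the exact sum of its
configured feature contributions, which is what makes the recovery
tests sharp.

Default sizes are scaled to desk hardware: two chromosomes of 60 Mb
and 40 Mb stand in for the two tiled chromosomes; 24 break sites with
~0.3 Mb domain halfwidths keep the fraction of probes inside spreading
domains (~15%) comparable to the real design, which is what the
percentile-threshold caller is sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .intervals import empty_genes, empty_sites, empty_zones, make_genes, make_sites, make_zones
from .tracks import ProbeTrack

__all__ = [
    "GenomeModel",
    "SynthConfig",
    "TruthSet",
    "TRACK_NAMES",
    "make_genome",
    "place_features",
    "simulate_tracks",
    "simulate_hic",
    "write_fixture",
    "read_fixture",
    "simulate_fixture",
]

TRACK_NAMES = (
    "gH2AX_ctrl_m4OHT",
    "gH2AX_ctrl_p4OHT",
    "gH2AX_depl_m4OHT",
    "gH2AX_depl_p4OHT",
    "cohesin_m4OHT",
    "cohesin_p4OHT",
    "input",
)


class GenerationError(RuntimeError):
    """Feature placement could not satisfy its packing constraints."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus a regular probe grid."""

    chromosomes: tuple[tuple[str, int], ...]
    probe_spacing: int = 35

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")

    def lengths(self) -> dict[str, int]:
        return {name: int(length) for name, length in self.chromosomes}

    def probes(self, chrom: str) -> np.ndarray:
        """Probe positions 0, spacing, 2*spacing, ... covering [0, length)."""
        length = self.lengths()[chrom]
        return np.arange(0, length, self.probe_spacing, dtype=np.int64)


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs of the generator (all signal units are log2)."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 60_000_000), ("chr6", 40_000_000))
    probe_spacing: int = 35
    baseline: float = 0.0
    n_dsb_sites: int = 24
    domain_halfwidth_mean: float = 300_000.0
    domain_halfwidth_sd: float = 80_000.0
    domain_amplitude: float = 1.0
    taper_fraction: float = 0.1          # edge taper width as a fraction of halfwidth
    holes_per_domain: int = 3
    hole_width_bp: float = 8_000.0
    hole_depth: float = 1.0
    n_cohesin_peaks: int = 300
    cohesin_peak_width_bp: float = 1_000.0
    cohesin_peak_amplitude: float = 1.5
    tss_fraction: float = 0.7            # fraction of peaks centred within 1 kb of a TSS
    dsb_local_halfwidth_bp: float = 2_500.0
    dsb_local_amplitude: float = 0.5
    noise_sd: float = 0.3
    depletion_effect: float = 0.4        # extra gH2AX on cohesin-bound probes, depleted +4OHT
    n_genes: int = 600
    gene_length_median_bp: float = 20_000.0
    gene_length_sigma: float = 0.6

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("n_dsb_sites", "holes_per_domain", "n_cohesin_peaks", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("domain_halfwidth_mean", "hole_width_bp", "cohesin_peak_width_bp",
                     "dsb_local_halfwidth_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.tss_fraction <= 1):
            raise ValueError("tss_fraction must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground-truth features behind a simulated fixture."""

    dsb_sites: pd.DataFrame = field(default_factory=empty_sites)
    true_domains: pd.DataFrame = field(default_factory=empty_zones)
    true_holes: pd.DataFrame = field(default_factory=empty_zones)
    true_cohesin_peaks: pd.DataFrame = field(default_factory=empty_zones)
    genes: pd.DataFrame = field(default_factory=empty_genes)


def make_genome(config: SynthConfig) -> GenomeModel:
    return GenomeModel(chromosomes=tuple(config.chromosomes),
                       probe_spacing=config.probe_spacing)


def _allocate_counts(total: int, lengths: list[int]) -> list[int]:
    """Deterministically split `total` across chromosomes by length."""
    if total == 0 or not lengths:
        return [0] * len(lengths)
    weights = np.asarray(lengths, dtype=float)
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    # hand out the remainder to the largest fractional parts (ties by order)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    for k in range(remainder):
        counts[order[k]] += 1
    return counts.tolist()


def place_features(genome: GenomeModel, config: SynthConfig,
                   seed: int | None = None) -> TruthSet:
    """Place break sites, domains, holes, cohesin peaks and genes.

    Break sites are placed one per equal-width slot of their chromosome
    (jittered within the slot) so that domains never overlap and sit at
    least twice their halfwidth from the chromosome ends whenever the
    slot allows it; an infeasible packing raises
    :class:`GenerationError` naming the constraint.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lengths = genome.lengths()
    chrom_names = list(lengths)
    chrom_lens = [lengths[c] for c in chrom_names]

    # --- genes -------------------------------------------------------
    gene_records = []
    for chrom, count in zip(chrom_names, _allocate_counts(config.n_genes, chrom_lens)):
        L = lengths[chrom]
        glen = np.minimum(
            rng.lognormal(np.log(config.gene_length_median_bp),
                          config.gene_length_sigma, size=count).astype(np.int64) + 1,
            max(L // 4, 1),
        )
        starts = rng.integers(0, np.maximum(L - glen, 1), size=count)
        strands = rng.choice(["+", "-"], size=count)
        for k in range(count):
            gene_records.append(
                {
                    "name": f"{chrom}_gene{k}",
                    "chrom": chrom,
                    "strand": str(strands[k]),
                    "tx_start": int(starts[k]),
                    "tx_end": int(starts[k] + glen[k]),
                }
            )
    genes = make_genes(gene_records)

    # --- DSB sites and their domains ---------------------------------
    site_records: list[tuple[str, int]] = []
    domain_records = []
    for chrom, count in zip(chrom_names, _allocate_counts(config.n_dsb_sites, chrom_lens)):
        if count == 0:
            continue
        L = lengths[chrom]
        slot = L / count
        halfwidths = np.clip(
            rng.normal(config.domain_halfwidth_mean, config.domain_halfwidth_sd, size=count),
            0.2 * config.domain_halfwidth_mean if config.domain_halfwidth_mean > 0 else 0,
            None,
        )
        for k in range(count):
            hw = float(halfwidths[k])
            margin = 2.0 * hw
            lo = k * slot + margin
            hi = (k + 1) * slot - margin
            if hi <= lo:
                # slot too small for the end margin; fall back to fitting
                # the domain itself, or fail if even that is impossible
                lo = k * slot + hw
                hi = (k + 1) * slot - hw
                if hi <= lo:
                    raise GenerationError(
                        f"{chrom}: cannot fit {count} domains of halfwidth ~{hw:.0f} bp "
                        f"into slots of {slot:.0f} bp (reduce n_dsb_sites or halfwidth)"
                    )
            site = int(rng.uniform(lo, hi))
            site_records.append((chrom, site))
            domain_records.append(
                {
                    "chrom": chrom,
                    "start": int(site - hw),
                    "end": int(site + hw),
                    "n_probes": 0,
                    "mean_score": config.domain_amplitude,
                    "label": "domain",
                }
            )
    dsb_sites = make_sites([c for c, _ in site_records], [p for _, p in site_records]) \
        if site_records else empty_sites()
    true_domains = make_zones(domain_records)

    # --- cohesin peaks ------------------------------------------------
    peak_records = []
    n_peaks = config.n_cohesin_peaks
    n_at_tss = int(round(config.tss_fraction * n_peaks)) if len(genes) else 0
    pw = config.cohesin_peak_width_bp
    if n_at_tss > 0:
        chosen = rng.choice(len(genes), size=n_at_tss, replace=n_at_tss > len(genes))
        for gi in chosen:
            g = genes.iloc[int(gi)]
            center = int(g["tss"]) + int(rng.integers(-500, 501))
            start = max(int(center - pw / 2), 0)
            end = min(int(start + pw), lengths[g["chrom"]])
            if end > start:
                peak_records.append(
                    {"chrom": g["chrom"], "start": start, "end": end, "n_probes": 0,
                     "mean_score": config.cohesin_peak_amplitude, "label": "peak"}
                )
    for chrom, count in zip(
        chrom_names, _allocate_counts(n_peaks - len(peak_records), chrom_lens)
    ):
        L = lengths[chrom]
        for _ in range(count):
            start = int(rng.integers(0, max(int(L - pw), 1)))
            peak_records.append(
                {"chrom": chrom, "start": start, "end": min(int(start + pw), L),
                 "n_probes": 0, "mean_score": config.cohesin_peak_amplitude, "label": "peak"}
            )
    true_cohesin_peaks = make_zones(peak_records)

    # --- holes: prefer cohesin peaks inside each domain ---------------
    hole_records = []
    spacing = genome.probe_spacing
    for _, dom in true_domains.iterrows():
        chrom = dom["chrom"]
        d_start, d_end = int(dom["start"]), int(dom["end"])
        # holes stay clear of the domain edges by one hole-width so the
        # true boundary remains identifiable from the signal
        margin = max(spacing, int(config.hole_width_bp))
        inner_lo = d_start + margin
        inner_hi = d_end - margin
        if inner_hi - inner_lo < config.hole_width_bp or config.holes_per_domain == 0:
            continue
        peaks_inside = true_cohesin_peaks[
            (true_cohesin_peaks["chrom"] == chrom)
            & (true_cohesin_peaks["start"] >= inner_lo)
            & (true_cohesin_peaks["end"] <= inner_hi)
        ]
        centers = [
            int((p["start"] + p["end"]) // 2)
            for _, p in peaks_inside.head(config.holes_per_domain).iterrows()
        ]
        while len(centers) < config.holes_per_domain:
            centers.append(int(rng.uniform(inner_lo + config.hole_width_bp / 2,
                                           inner_hi - config.hole_width_bp / 2)))
        for center in centers:
            h_start = max(int(center - config.hole_width_bp / 2), inner_lo)
            h_end = min(int(h_start + config.hole_width_bp), inner_hi)
            if h_end > h_start:
                hole_records.append(
                    {"chrom": chrom, "start": h_start, "end": h_end, "n_probes": 0,
                     "mean_score": config.hole_depth, "label": "hole"}
                )
    true_holes = merge_truth_holes(make_zones(hole_records))

    return TruthSet(
        dsb_sites=dsb_sites,
        true_domains=true_domains,
        true_holes=true_holes,
        true_cohesin_peaks=true_cohesin_peaks,
        genes=genes,
    )


def merge_truth_holes(holes: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping truth holes so the truth set is non-overlapping."""
    if holes.empty:
        return holes
    out = []
    for chrom, sub in holes.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        cur = sub.iloc[0].to_dict()
        for _, h in sub.iloc[1:].iterrows():
            if h["start"] < cur["end"]:
                cur["end"] = max(cur["end"], int(h["end"]))
            else:
                out.append(cur)
                cur = h.to_dict()
        out.append(cur)
    return make_zones(out)


def _interval_mask(pos: np.ndarray, zones: pd.DataFrame, chrom: str) -> np.ndarray:
    mask = np.zeros(pos.size, dtype=bool)
    sub = zones[zones["chrom"] == chrom]
    for _, z in sub.iterrows():
        i = np.searchsorted(pos, z["start"], side="left")
        j = np.searchsorted(pos, z["end"], side="left")
        mask[i:j] = True
    return mask


def _domain_contribution(pos: np.ndarray, truth: TruthSet, config: SynthConfig,
                         chrom: str) -> np.ndarray:
    """Plateau of ``domain_amplitude`` with a linear edge taper, minus holes."""
    out = np.zeros(pos.size)
    doms = truth.true_domains[truth.true_domains["chrom"] == chrom]
    for _, d in doms.iterrows():
        s, e = int(d["start"]), int(d["end"])
        hw = (e - s) / 2.0
        tw = config.taper_fraction * hw
        i = np.searchsorted(pos, s, side="left")
        j = np.searchsorted(pos, e, side="left")
        p = pos[i:j].astype(float)
        if tw > 0:
            ramp = np.minimum(np.minimum(p - s, e - p) / tw, 1.0)
            ramp = np.clip(ramp, 0.0, 1.0)
        else:
            ramp = 1.0
        out[i:j] += config.domain_amplitude * ramp
    hole_mask = _interval_mask(pos, truth.true_holes, chrom)
    out[hole_mask] -= config.hole_depth
    return out


def _dsb_bump(pos: np.ndarray, truth: TruthSet, config: SynthConfig,
              chrom: str) -> np.ndarray:
    """Triangular local cohesin enrichment centred on each break site."""
    out = np.zeros(pos.size)
    hw = config.dsb_local_halfwidth_bp
    if hw <= 0 or config.dsb_local_amplitude == 0:
        return out
    sites = truth.dsb_sites[truth.dsb_sites["chrom"] == chrom]
    for _, s in sites.iterrows():
        c = int(s["pos"])
        i = np.searchsorted(pos, c - hw, side="left")
        j = np.searchsorted(pos, c + hw, side="right")
        p = pos[i:j].astype(float)
        out[i:j] += config.dsb_local_amplitude * np.clip(1.0 - np.abs(p - c) / hw, 0.0, 1.0)
    return out


def simulate_tracks(genome: GenomeModel, truth: TruthSet, config: SynthConfig,
                    seed: int | None = None,
                    names: tuple[str, ...] = TRACK_NAMES) -> dict[str, ProbeTrack]:
    """Simulate the named probe tracks (log2-ratio scale).

    Per-probe value = baseline + feature contributions + N(0, noise_sd);
    contributions per track:

    * ``gH2AX_*_p4OHT``: domain plateau (tapered) minus hole depth; the
      depleted condition additionally gains ``depletion_effect`` on
      probes inside cohesin peaks.
    * ``cohesin_*``: peak amplitude on peak probes; ``cohesin_p4OHT``
      additionally carries the local break-site bump.
    * ``gH2AX_*_m4OHT`` and ``input``: baseline only.
    """
    unknown = set(names) - set(TRACK_NAMES)
    if unknown:
        raise ValueError(f"unknown track name(s) {sorted(unknown)}; "
                         f"valid names: {list(TRACK_NAMES)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tracks: dict[str, ProbeTrack] = {}
    chrom_names = list(genome.lengths())
    # noise is drawn in a fixed (track, chromosome) order so a fixture is
    # reproducible regardless of which subset of tracks is requested
    noise = {
        (tname, chrom): (rng.normal(0.0, config.noise_sd, size=genome.probes(chrom).size)
                         if config.noise_sd > 0 else 0.0)
        for tname in TRACK_NAMES
        for chrom in chrom_names
    }
    for tname in names:
        track = ProbeTrack(name=tname, kind="log2_ratio")
        for chrom in chrom_names:
            pos = genome.probes(chrom)
            val = np.full(pos.size, config.baseline, dtype=float)
            if tname in ("gH2AX_ctrl_p4OHT", "gH2AX_depl_p4OHT"):
                val += _domain_contribution(pos, truth, config, chrom)
            if tname == "gH2AX_depl_p4OHT" and config.depletion_effect != 0:
                val += config.depletion_effect * _interval_mask(
                    pos, truth.true_cohesin_peaks, chrom
                )
            if tname in ("cohesin_m4OHT", "cohesin_p4OHT"):
                val += config.cohesin_peak_amplitude * _interval_mask(
                    pos, truth.true_cohesin_peaks, chrom
                )
            if tname == "cohesin_p4OHT":
                val += _dsb_bump(pos, truth, config, chrom)
            val = val + noise[(tname, chrom)]
            track.add_chromosome(chrom, pos, val)
        tracks[tname] = track
    return tracks


def simulate_hic(genome: GenomeModel, truth: TruthSet, bin_bp: int,
                 seed: int | None = None, in_block_mean: float = 10.0,
                 background_mean: float = 1.0,
                 noise_sd: float = 0.0) -> dict[str, np.ndarray]:
    """Block-diagonal contact matrices: bins sharing a truth domain
    interact at ``in_block_mean``, all other pairs at ``background_mean``.

    Matrices are exactly symmetric (noise is drawn on the upper triangle
    and reflected) and clipped to be non-negative.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    rng = np.random.default_rng(seed if seed is not None else 0)
    out = {}
    for chrom, length in genome.lengths().items():
        n_bins = int(np.ceil(length / bin_bp))
        mat = np.full((n_bins, n_bins), float(background_mean))
        mids = (np.arange(n_bins) + 0.5) * bin_bp
        doms = truth.true_domains[truth.true_domains["chrom"] == chrom]
        for _, d in doms.iterrows():
            inside = np.flatnonzero((mids >= d["start"]) & (mids < d["end"]))
            if inside.size:
                mat[np.ix_(inside, inside)] = float(in_block_mean)
        if noise_sd > 0:
            upper = rng.normal(0.0, noise_sd, size=(n_bins, n_bins))
            upper = np.triu(upper)
            mat = mat + upper + np.triu(upper, 1).T
        out[chrom] = np.clip(mat, 0.0, None)
    return out


# ---------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------

def write_fixture(directory, genome: GenomeModel, truth: TruthSet,
                  tracks: dict[str, ProbeTrack],
                  matrices: dict[str, np.ndarray] | None = None,
                  bin_bp: int | None = None) -> None:
    """Write a full fixture: bedGraph per track, BEDs for truth features,
    refFlat for genes, chrom sizes, and optional contact matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "chrom.sizes", "w") as fh:
        for name, length in genome.lengths().items():
            fh.write(f"{name}\t{length}\t{genome.probe_spacing}\n")
    for tname, track in tracks.items():
        formats.write_bedgraph(track, directory / f"{tname}.bedGraph")
    formats.write_bed_sites(truth.dsb_sites, directory / "dsb_sites.bed")
    formats.write_bed_zones(truth.true_domains, directory / "true_domains.bed")
    formats.write_bed_zones(truth.true_holes, directory / "true_holes.bed")
    formats.write_bed_zones(truth.true_cohesin_peaks, directory / "true_cohesin_peaks.bed")
    formats.write_refflat(truth.genes, directory / "genes.refFlat")
    if matrices is not None:
        if bin_bp is None:
            raise ValueError("bin_bp is required when writing matrices")
        for chrom, mat in matrices.items():
            formats.write_matrix(mat, bin_bp, chrom, directory / f"hic_{chrom}.matrix.txt")


def read_fixture(directory) -> tuple[GenomeModel, TruthSet, dict[str, ProbeTrack]]:
    """Round-trip companion of :func:`write_fixture` (tracks + truth)."""
    directory = Path(directory)
    chromosomes = []
    spacing = None
    with open(directory / "chrom.sizes") as fh:
        for line in fh:
            name, length, sp = line.split("\t")
            chromosomes.append((name, int(length)))
            spacing = int(sp)
    genome = GenomeModel(chromosomes=tuple(chromosomes), probe_spacing=spacing)
    tracks = {}
    for path in sorted(directory.glob("*.bedGraph")):
        tracks[path.stem] = formats.read_bedgraph(path)
    truth = TruthSet(
        dsb_sites=formats.read_bed_sites(directory / "dsb_sites.bed"),
        true_domains=formats.read_bed_zones(directory / "true_domains.bed"),
        true_holes=formats.read_bed_zones(directory / "true_holes.bed"),
        true_cohesin_peaks=formats.read_bed_zones(directory / "true_cohesin_peaks.bed"),
        genes=formats.read_refflat(directory / "genes.refFlat"),
    )
    return genome, truth, tracks


def simulate_fixture(config: SynthConfig, seed: int | None = None,
                     names: tuple[str, ...] = TRACK_NAMES
                     ) -> tuple[GenomeModel, TruthSet, dict[str, ProbeTrack]]:
    """Convenience: genome + truth + tracks in one call."""
    genome = make_genome(config)
    truth = place_features(genome, config, seed=seed)
    tracks = simulate_tracks(genome, truth, config, seed=None if seed is None else seed + 1,
                             names=names)
    return genome, truth, tracks
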