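"""Seed-and-extend calling of enriched zones on tiling-array signal.

The caller finds enriched intervals of any size in two steps:

1. *Seeding* — every window of ``n_seed`` consecutive probes containing
   at least ``min_above`` probes with value strictly above a
   per-chromosome threshold ``T`` qualifies; the union of qualifying
   windows, split into maximal runs, gives the candidate zones.
2. *Extension* — each candidate edge advances probe-by-probe while the
   ``ext_window`` probes ending at the tentative new edge keep more than
   ``ext_fraction * ext_window`` probes above ``T``; the left edge is
   refined before the right one, and extension never crosses a
   chromosome end or a neighbouring seed.

Candidates closer than ``merge_gap_bp`` are then coalesced and the
result filtered on probe count, bp length and mean score.  ``T`` is the
nearest-rank percentile of the chromosome's values.

The same machinery is applied three ways: broad gamma-H2AX spreading
domains, narrow cohesin peaks (the classic 20-probe / 17-above setting),
and depleted "holes" inside previously called domains (the caller run on
the negated in-domain signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .intervals import BOUNDARY_COLUMNS, empty_zones, make_zones
from .tracks import ProbeTrack

__all__ = [
    "CallerParams",
    "PRESETS",
    "percentile_threshold",
    "find_seed_zones",
    "extend_zone",
    "merge_zones",
    "filter_zones",
    "call_enriched_domains",
    "call_holes",
    "domain_boundaries",
]


@dataclass(frozen=True)
class CallerParams:
    """Parameters of the two-step caller.

    ``n_seed`` / ``min_above`` define the seed rule ("N probes of which
    at least m above threshold"); ``threshold_percentile`` the
    per-chromosome nearest-rank percentile giving T; ``ext_window`` /
    ``ext_fraction`` the edge-refinement rule (default: same as the seed
    rule); ``merge_gap_bp`` and the ``min_*`` fields the merge/filter
    stage.
    """

    n_seed: int = 50
    min_above: int = 40
    threshold_percentile: float = 70.0
    ext_window: int | None = None
    ext_fraction: float | None = None
    merge_gap_bp: int = 30_000
    min_probes: int = 0
    min_bp: int = 50_000
    min_mean_score: float = -math.inf
    label: str = "domain"

    def __post_init__(self):
        if not (1 <= self.min_above <= self.n_seed):
            raise ValueError("need 1 <= min_above <= n_seed")
        if not (0 < self.threshold_percentile < 100):
            raise ValueError("threshold_percentile must be in (0, 100)")
        ef = self.effective_ext_fraction
        if not (0 <= ef <= 1):
            raise ValueError("ext_fraction must be in [0, 1]")
        if self.effective_ext_window < 1:
            raise ValueError("ext_window must be >= 1")

    @property
    def effective_ext_window(self) -> int:
        return self.n_seed if self.ext_window is None else self.ext_window

    @property
    def effective_ext_fraction(self) -> float:
        return (self.min_above / self.n_seed
                if self.ext_fraction is None else self.ext_fraction)


#: Ready-made parameter sets.  The ``cohesin_peaks`` numbers (20-probe
#: seeds, >=17 above, 90th percentile) are the published peak-calling
#: setting; the domain and hole presets are this package's defaults,
#: chosen for megabase-scale spreading domains on ~35 bp probe grids
#: and kilobase-scale depleted holes respectively.
PRESETS: dict[str, CallerParams] = {
    "gammaH2AX_domains": CallerParams(
        n_seed=50, min_above=40, threshold_percentile=70.0,
        merge_gap_bp=30_000, min_bp=50_000, label="domain",
    ),
    "cohesin_peaks": CallerParams(
        n_seed=20, min_above=17, threshold_percentile=90.0,
        merge_gap_bp=500, min_bp=0, label="peak",
    ),
    "holes": CallerParams(
        n_seed=20, min_above=14, threshold_percentile=90.0,
        merge_gap_bp=1_000, min_bp=2_000, label="hole",
    ),
}


def percentile_threshold(values, pct: float) -> float:
    """Nearest-rank percentile: the sorted value at 1-based rank
    ``ceil(pct/100 * n)`` (no interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of no values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not (0 < pct < 100):
        raise ValueError("pct must be in (0, 100)")
    rank = math.ceil(pct / 100.0 * values.size)  # 1-based
    return float(np.sort(values)[rank - 1])


def find_seed_zones(values: np.ndarray, threshold: float, n_seed: int,
                    min_above: int) -> list[tuple[int, int]]:
    """Maximal runs of probe indices covered by qualifying seed windows.

    A window of ``n_seed`` consecutive probes qualifies when it holds at
    least ``min_above`` probes with value strictly above ``threshold``.
    Returns half-open probe-index intervals ``[i, j)``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_seed:
        return []
    above = values > threshold
    window_counts = np.convolve(above.astype(np.int64), np.ones(n_seed, dtype=np.int64),
                                mode="valid")
    qualifying = np.flatnonzero(window_counts >= min_above)  # window start indices
    if qualifying.size == 0:
        return []
    # a qualifying start s covers probes [s, s + n_seed); mark via diff trick
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, qualifying, 1)
    np.add.at(diff, np.minimum(qualifying + n_seed, n), -1)
    covered = np.cumsum(diff[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.astype(np.int8), [0]])))
    return [(int(edges[k]), int(edges[k + 1])) for k in range(0, edges.size, 2)]


def extend_zone(values: np.ndarray, zone: tuple[int, int], threshold: float,
                ext_window: int, ext_fraction: float,
                lo: int = 0, hi: int | None = None) -> tuple[int, int]:
    """Refine a seed's probe-index limits by bidirectional extension.

    Each side advances one probe at a time while the ``ext_window``
    probes ending at the tentative new edge (looking back into the zone)
    contain strictly more than ``ext_fraction * ext_window`` probes
    above threshold; windows truncated by ``lo``/``hi`` use their actual
    length.  The left side is refined first.  ``lo``/``hi`` bound the
    extension (chromosome end or neighbouring seed).
    """
    values = np.asarray(values, dtype=float)
    if hi is None:
        hi = values.size
    above = values > threshold
    start, end = zone

    # left edge: tentative new first probe j; window [j, j + ext_window)
    j = start - 1
    while j >= lo:
        w_end = min(j + ext_window, hi)
        window = above[j:w_end]
        if window.sum() > ext_fraction * window.size:
            j -= 1
        else:
            break
    start = j + 1

    # right edge: tentative new last probe j; window (j - ext_window, j]
    j = end  # index of the tentative new last probe
    while j < hi:
        w_start = max(j - ext_window + 1, lo)
        window = above[w_start:j + 1]
        if window.sum() > ext_fraction * window.size:
            j += 1
        else:
            break
    end = j

    return (start, end)


def _zone_record(chrom: str, pos: np.ndarray, values: np.ndarray,
                 i: int, j: int, label: str) -> dict:
    return {
        "chrom": chrom,
        "start": int(pos[i]),
        "end": int(pos[j - 1]) + 1,
        "n_probes": int(j - i),
        "mean_score": float(values[i:j].mean()),
        "label": label,
    }


def merge_zones(zones: pd.DataFrame, merge_gap_bp: int,
                track: ProbeTrack | None = None) -> pd.DataFrame:
    """Coalesce same-chromosome zones whose gap is < ``merge_gap_bp``.

    Overlapping or touching zones are always coalesced.  When ``track``
    is given, ``n_probes`` and ``mean_score`` are recomputed over all
    probes spanned by each merged zone; otherwise member probe counts
    are summed and scores combined as a probe-weighted mean.
    """
    if zones.empty:
        return zones.copy()
    out = []
    for chrom, sub in zones.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        cur = sub.iloc[0].to_dict()
        for _, z in sub.iloc[1:].iterrows():
            if z["start"] - cur["end"] < merge_gap_bp or z["start"] < cur["end"]:
                total = cur["n_probes"] + z["n_probes"]
                if total > 0:
                    cur["mean_score"] = (
                        cur["mean_score"] * cur["n_probes"] + z["mean_score"] * z["n_probes"]
                    ) / total
                cur["n_probes"] = total
                cur["end"] = max(cur["end"], int(z["end"]))
            else:
                out.append(cur)
                cur = z.to_dict()
        out.append(cur)
    merged = make_zones(out)
    if track is not None:
        merged = _rescore(merged, track)
    return merged


def _rescore(zones: pd.DataFrame, track: ProbeTrack) -> pd.DataFrame:
    """Recompute n_probes / mean_score over every probe within each span."""
    zones = zones.copy()
    for idx, z in zones.iterrows():
        pos = track.positions(z["chrom"])
        val = track.values(z["chrom"])
        i = int(np.searchsorted(pos, z["start"], side="left"))
        j = int(np.searchsorted(pos, z["end"], side="left"))
        zones.at[idx, "n_probes"] = j - i
        zones.at[idx, "mean_score"] = float(val[i:j].mean()) if j > i else np.nan
    return zones


def filter_zones(zones: pd.DataFrame, min_probes: int = 0, min_bp: int = 0,
                 min_mean_score: float = -math.inf) -> pd.DataFrame:
    """Keep zones meeting all of the probe-count, length and score floors."""
    if zones.empty:
        return zones.copy()
    keep = (
        (zones["n_probes"] >= min_probes)
        & ((zones["end"] - zones["start"]) >= min_bp)
        & (zones["mean_score"] >= min_mean_score)
    )
    return zones[keep].reset_index(drop=True)


def call_enriched_domains(track: ProbeTrack, params: CallerParams,
                          threshold: float | None = None) -> pd.DataFrame:
    """Full caller: per-chromosome threshold, seed, extend, merge, filter.

    ``threshold`` overrides the percentile rule with a fixed T for every
    chromosome (used by the hole caller, which thresholds on the pooled
    in-domain values).
    """
    records = []
    for chrom in track.chroms():
        pos = track.positions(chrom)
        val = track.values(chrom)
        if val.size == 0:
            continue
        T = percentile_threshold(val, params.threshold_percentile) \
            if threshold is None else threshold
        seeds = find_seed_zones(val, T, params.n_seed, params.min_above)
        ew = params.effective_ext_window
        ef = params.effective_ext_fraction
        for k, seed in enumerate(seeds):
            lo = seeds[k - 1][1] if k > 0 else 0
            hi = seeds[k + 1][0] if k + 1 < len(seeds) else val.size
            i, j = extend_zone(val, seed, T, ew, ef, lo=lo, hi=hi)
            records.append(_zone_record(chrom, pos, val, i, j, params.label))
    zones = make_zones(records)
    zones = merge_zones(zones, params.merge_gap_bp, track=track)
    return filter_zones(zones, params.min_probes, params.min_bp, params.min_mean_score)


def call_holes(track: ProbeTrack, domains: pd.DataFrame,
               params: CallerParams | None = None) -> pd.DataFrame:
    """Call depleted holes inside previously called domains.

    The caller is run on the negated signal restricted to the probes of
    each domain; the threshold is the nearest-rank percentile of the
    pooled negated in-domain values of the chromosome.  Holes are by
    construction contained in their parent domain.
    """
    if params is None:
        params = PRESETS["holes"]
    params = replace(params, label="hole")
    if domains.empty:
        return empty_zones()
    records = []
    for chrom, doms in domains.groupby("chrom", sort=True):
        pos = track.positions(chrom)
        val = track.values(chrom)
        spans = []
        pooled = []
        for _, d in doms.iterrows():
            i = int(np.searchsorted(pos, d["start"], side="left"))
            j = int(np.searchsorted(pos, d["end"], side="left"))
            if j > i:
                spans.append((i, j))
                pooled.append(-val[i:j])
        if not spans:
            continue
        T = percentile_threshold(np.concatenate(pooled), params.threshold_percentile)
        ew = params.effective_ext_window
        ef = params.effective_ext_fraction
        for i, j in spans:
            neg = -val[i:j]
            seeds = find_seed_zones(neg, T, params.n_seed, params.min_above)
            for k, seed in enumerate(seeds):
                lo = seeds[k - 1][1] if k > 0 else 0
                hi = seeds[k + 1][0] if k + 1 < len(seeds) else neg.size
                a, b = extend_zone(neg, seed, T, ew, ef, lo=lo, hi=hi)
                records.append(_zone_record(chrom, pos[i:j], neg, a, b, "hole"))
    holes = make_zones(records)
    holes = merge_zones(holes, params.merge_gap_bp)
    # rescore on the negated track values so mean_score is depletion depth
    for idx, h in holes.iterrows():
        pos = track.positions(h["chrom"])
        val = track.values(h["chrom"])
        i = int(np.searchsorted(pos, h["start"], side="left"))
        j = int(np.searchsorted(pos, h["end"], side="left"))
        holes.at[idx, "n_probes"] = j - i
        holes.at[idx, "mean_score"] = float(-val[i:j].mean()) if j > i else np.nan
    return filter_zones(holes, params.min_probes, params.min_bp, params.min_mean_score)


def domain_boundaries(domains: pd.DataFrame) -> pd.DataFrame:
    """Two labelled boundaries per zone: (start, left) and (end, right)."""
    records = []
    for zone_id, (_, z) in enumerate(domains.iterrows()):
        records.append({"chrom": z["chrom"], "pos": int(z["start"]),
                        "side": "left", "zone_id": zone_id})
        records.append({"chrom": z["chrom"], "pos": int(z["end"]),
                        "side": "right", "zone_id": zone_id})
    if not records:
        return pd.DataFrame(columns=BOUNDARY_COLUMNS)
    return pd.DataFrame.from_records(records, columns=BOUNDARY_COLUMNS)
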