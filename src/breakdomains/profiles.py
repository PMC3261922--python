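"""Anchor-relative averaging (metaprofiles) with mirroring.

Profiles pool all (anchor, probe) pairs whose offset falls in each bin,
rather than averaging per anchor first; anchors near chromosome ends
simply contribute partial windows.  Offset bins are half-open
``[k*w, (k+1)*w)`` so offset 0 falls in the first non-negative bin, and
the reported offset grid is the bin centers.

Mirroring conventions: for zone boundaries the left border is mirrored
(offset = boundary - pos) so negative offsets always point into the
zone; for contact-matrix pileups the right boundary's submatrix is
flipped along both axes before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import ProbeTrack

__all__ = [
    "MetaProfile",
    "site_profile",
    "boundary_overlay",
    "tss_profile",
    "genes_in_domains",
    "hic_boundary_pileup",
]


@dataclass
class MetaProfile:
    """Mean signal per offset bin relative to a set of anchors.

    ``n`` counts the contributing (anchor, probe) pairs per bin;
    ``n_anchors`` the distinct anchors contributing at least one pair.
    ``mean`` is NaN where ``n == 0``.
    """

    offsets: np.ndarray       # bin centers, bp
    mean: np.ndarray
    n: np.ndarray
    n_anchors: np.ndarray
    window_bp: float          # bin width used for averaging
    half_window_bp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.n,
             "n_anchors": self.n_anchors}
        )


def _pooled_profile(track: ProbeTrack, anchors: list[tuple[str, int, int]],
                    half_window_bp: float, avg_window_bp: float) -> MetaProfile:
    """Pool (anchor, probe) pairs into offset bins.

    ``anchors`` are (chrom, position, sign) with sign +1 for as-is
    orientation and -1 for mirrored (offset = anchor - pos).
    """
    if not anchors:
        raise ValueError("anchor list is empty")
    if avg_window_bp <= 0 or half_window_bp <= 0:
        raise ValueError("window sizes must be > 0")
    w = float(avg_window_bp)
    nb = int(np.ceil(half_window_bp / w))
    ks = np.arange(-nb, nb)
    sums = np.zeros(ks.size)
    counts = np.zeros(ks.size, dtype=np.int64)
    anchor_counts = np.zeros(ks.size, dtype=np.int64)
    for chrom, apos, sign in anchors:
        if chrom not in track.chroms():
            continue
        pos = track.positions(chrom)
        val = track.values(chrom)
        # probes whose offset can land in [-nb*w, nb*w)
        if sign >= 0:
            lo = np.searchsorted(pos, apos - nb * w, side="left")
            hi = np.searchsorted(pos, apos + nb * w, side="left")
            offs = pos[lo:hi].astype(float) - apos
        else:
            lo = np.searchsorted(pos, apos - nb * w, side="right")
            hi = np.searchsorted(pos, apos + nb * w, side="right")
            offs = apos - pos[lo:hi].astype(float)
        if lo >= hi:
            continue
        k = np.floor(offs / w).astype(np.int64)
        inside = (k >= -nb) & (k < nb)
        k = k[inside] + nb
        v = val[lo:hi][inside]
        np.add.at(sums, k, v)
        np.add.at(counts, k, 1)
        anchor_counts[np.unique(k)] += 1
    mean = np.full(ks.size, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return MetaProfile(
        offsets=(ks + 0.5) * w,
        mean=mean,
        n=counts,
        n_anchors=anchor_counts,
        window_bp=w,
        half_window_bp=float(half_window_bp),
    )


def site_profile(track: ProbeTrack, sites: pd.DataFrame, half_window_bp: float,
                 avg_window_bp: float) -> MetaProfile:
    """Average signal around point anchors (e.g. break sites)."""
    if sites.empty:
        raise ValueError("site list is empty")
    anchors = [(str(s["chrom"]), int(s["pos"]), +1) for _, s in sites.iterrows()]
    return _pooled_profile(track, anchors, half_window_bp, avg_window_bp)


def boundary_overlay(track: ProbeTrack, boundaries: pd.DataFrame,
                     half_window_bp: float, avg_window_bp: float) -> MetaProfile:
    """Overlay zone borders; left borders are mirrored so negative
    offsets always point into the zone."""
    if boundaries.empty:
        raise ValueError("boundary list is empty")
    anchors = []
    for _, b in boundaries.iterrows():
        side = b.get("side")
        if side not in ("left", "right"):
            raise ValueError(f"boundary at {b.get('chrom')}:{b.get('pos')} lacks a "
                             f"valid side label (got {side!r})")
        anchors.append((str(b["chrom"]), int(b["pos"]), +1 if side == "right" else -1))
    return _pooled_profile(track, anchors, half_window_bp, avg_window_bp)


def tss_profile(track: ProbeTrack, genes: pd.DataFrame, half_window_bp: float,
                avg_window_bp: float) -> MetaProfile:
    """TSS-oriented profile: minus-strand genes contribute mirrored so
    positive offsets always point in the direction of transcription."""
    if genes.empty:
        raise ValueError("gene table is empty")
    anchors = [
        (str(g["chrom"]), int(g["tss"]), +1 if g["strand"] == "+" else -1)
        for _, g in genes.iterrows()
    ]
    return _pooled_profile(track, anchors, half_window_bp, avg_window_bp)


def genes_in_domains(genes: pd.DataFrame, domains: pd.DataFrame,
                     mode: str = "intersect") -> pd.DataFrame:
    """Genes whose [tx_start, tx_end) intersects (or is contained in) a domain."""
    if mode not in ("intersect", "contain"):
        raise ValueError("mode must be 'intersect' or 'contain'")
    if genes.empty or domains.empty:
        return genes.iloc[0:0].copy()
    keep = np.zeros(len(genes), dtype=bool)
    for chrom, doms in domains.groupby("chrom"):
        sel = genes["chrom"] == chrom
        if not sel.any():
            continue
        gs = genes.loc[sel, "tx_start"].to_numpy()
        ge = genes.loc[sel, "tx_end"].to_numpy()
        hit = np.zeros(gs.size, dtype=bool)
        for _, d in doms.iterrows():
            if mode == "intersect":
                hit |= (gs < d["end"]) & (ge > d["start"])
            else:
                hit |= (gs >= d["start"]) & (ge <= d["end"])
        keep[np.flatnonzero(sel.to_numpy())] = hit
    return genes[keep].reset_index(drop=True)


def hic_boundary_pileup(matrices: dict[str, np.ndarray], bin_bp: int,
                        boundaries: pd.DataFrame,
                        half_window_bp: int) -> np.ndarray:
    """Element-wise mean of contact submatrices centred on boundaries.

    Each usable boundary contributes the square submatrix of half-size
    ``half_window_bp / bin_bp`` bins around its bin; right-side
    boundaries are flipped along both axes before averaging so the zone
    interior always lies on the positive-offset side.  Boundaries whose window
    would cross a matrix edge are skipped; if none are usable this is an
    error.
    """
    if half_window_bp % bin_bp != 0:
        raise ValueError("half_window_bp must be a multiple of bin_bp")
    h = half_window_bp // bin_bp
    subs = []
    n_skipped = 0
    for _, b in boundaries.iterrows():
        side = b.get("side")
        if side not in ("left", "right"):
            raise ValueError(f"boundary at {b.get('chrom')}:{b.get('pos')} lacks a "
                             f"valid side label (got {side!r})")
        chrom = str(b["chrom"])
        if chrom not in matrices:
            n_skipped += 1
            continue
        mat = matrices[chrom]
        bin_idx = int(b["pos"]) // bin_bp
        if bin_idx - h < 0 or bin_idx + h >= mat.shape[0]:
            n_skipped += 1
            continue
        sub = mat[bin_idx - h:bin_idx + h + 1, bin_idx - h:bin_idx + h + 1]
        if side == "right":
            sub = sub[::-1, ::-1]
        subs.append(np.asarray(sub, dtype=float))
    if not subs:
        raise ValueError(f"no usable boundary ({n_skipped} skipped at matrix edges)")
    return np.mean(subs, axis=0)
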