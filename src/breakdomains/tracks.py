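"""Probe-level signal tracks and the array-processing primitives.

A :class:`ProbeTrack` holds, per chromosome, a strictly increasing
vector of probe positions (bp, 0-based probe centers) and one numeric
value per probe — either a raw hybridization intensity or a log2
IP/input ratio.  Tiling-array probes are treated as points at the start
of their bedGraph interval; missing probes are simply absent, never NaN.

The module also implements the array-level preprocessing used
throughout the pipeline: cross-array quantile normalization with a
target scale, log2 ratio formation, and the two smoothing modes
(probe-count sliding windows for wide views, bp windows for
anchor-relative averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTrack",
    "quantile_normalize",
    "log2_ratio",
    "smooth_probes",
    "smooth_bp",
]


@dataclass
class ProbeTrack:
    """Per-chromosome probe positions + values.

    Parameters
    ----------
    name:
        Track label (e.g. ``"gH2AX_ctrl_p4OHT"``).
    kind:
        What the values are: ``"intensity"`` or ``"log2_ratio"``.
    """

    name: str = "track"
    kind: str = "log2_ratio"
    _pos: dict = field(default_factory=dict, repr=False)
    _val: dict = field(default_factory=dict, repr=False)

    # -- construction -------------------------------------------------
    def add_chromosome(self, chrom: str, positions, values) -> None:
        pos = np.asarray(positions, dtype=np.int64)
        val = np.asarray(values, dtype=np.float64)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ValueError(f"{chrom}: positions and values must be 1-D and equal length")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError(f"{chrom}: probe positions must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError(f"{chrom}: values must be finite (missing probes are absent, not NaN)")
        if chrom in self._pos:
            raise ValueError(f"chromosome {chrom} added twice")
        self._pos[chrom] = pos
        self._val[chrom] = val

    @classmethod
    def from_dict(cls, data: dict, name: str = "track", kind: str = "log2_ratio") -> "ProbeTrack":
        t = cls(name=name, kind=kind)
        for chrom, (pos, val) in data.items():
            t.add_chromosome(chrom, pos, val)
        return t

    # -- access -------------------------------------------------------
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos[chrom]

    def values(self, chrom: str) -> np.ndarray:
        return self._val[chrom]

    def n_probes(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self._pos[chrom].size)
        return int(sum(p.size for p in self._pos.values()))

    def all_values(self) -> np.ndarray:
        """Concatenated values over chromosomes (chromosome insertion order)."""
        if not self._val:
            return np.empty(0)
        return np.concatenate([self._val[c] for c in self._pos])

    def same_grid(self, other: "ProbeTrack") -> bool:
        if set(self._pos) != set(other._pos):
            return False
        return all(np.array_equal(self._pos[c], other._pos[c]) for c in self._pos)

    def with_values(self, new_values: dict, name: str | None = None,
                    kind: str | None = None) -> "ProbeTrack":
        """New track on the same probe grid with replaced value arrays."""
        t = ProbeTrack(name=name or self.name, kind=kind or self.kind)
        for chrom in self._pos:
            t.add_chromosome(chrom, self._pos[chrom], new_values[chrom])
        return t

    def copy(self, name: str | None = None) -> "ProbeTrack":
        return self.with_values({c: self._val[c].copy() for c in self._pos}, name=name)

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, ProbeTrack):
            return NotImplemented
        return self.same_grid(other) and all(
            np.array_equal(self._val[c], other._val[c]) for c in self._pos
        )


# ---------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------

def quantile_normalize(arrays: list[np.ndarray], scale: float = 500.0) -> list[np.ndarray]:
    """Quantile-normalize equal-length value arrays to a common target scale.

    Every output array has exactly the same sorted value vector (the
    across-array mean of the per-rank sorted values); tied input values
    receive the mean of the reference values spanned by their tie run.
    Afterwards each array is rescaled so its mean equals ``scale``
    (multiplicatively when the reference mean is positive, by an
    additive shift otherwise, so rank order is always preserved).
    """
    if len(arrays) < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    arrs = [np.asarray(a, dtype=np.float64) for a in arrays]
    n = arrs[0].size
    if n == 0:
        raise ValueError("cannot quantile-normalize empty arrays")
    for a in arrs:
        if a.ndim != 1 or a.size != n:
            raise ValueError("all arrays must be 1-D and of equal length")
        if not np.all(np.isfinite(a)):
            raise ValueError("arrays must be finite")

    reference = np.mean([np.sort(a) for a in arrs], axis=0)
    ref_mean = reference.mean()

    out = []
    for a in arrs:
        order = np.argsort(a, kind="mergesort")
        sorted_vals = a[order]
        # tie runs in sorted order share the mean of their reference span
        run_starts = np.flatnonzero(np.concatenate([[True], sorted_vals[1:] != sorted_vals[:-1]]))
        run_sums = np.add.reduceat(reference, run_starts)
        run_lens = np.diff(np.concatenate([run_starts, [n]]))
        run_means = run_sums / run_lens
        mapped = np.empty(n)
        mapped[order] = np.repeat(run_means, run_lens)
        out.append(mapped)

    if ref_mean > 0:
        out = [a * (scale / ref_mean) for a in out]
    else:
        out = [a + (scale - ref_mean) for a in out]
    return out


# ---------------------------------------------------------------------
# ratios and smoothing
# ---------------------------------------------------------------------

def log2_ratio(numerator: ProbeTrack, denominator: ProbeTrack,
               pseudocount: float = 0.0, name: str | None = None) -> ProbeTrack:
    """log2((num + pc) / (den + pc)) on a shared probe grid."""
    if set(numerator.chroms()) != set(denominator.chroms()):
        raise ValueError("tracks cover different chromosomes")
    new = {}
    for chrom in numerator.chroms():
        pa, pb = numerator.positions(chrom), denominator.positions(chrom)
        if not np.array_equal(pa, pb):
            m = min(pa.size, pb.size)
            diff = np.flatnonzero(pa[:m] != pb[:m])
            i = int(diff[0]) if diff.size else m
            where = int(pa[i]) if i < pa.size else int(pb[i])
            raise ValueError(f"{chrom}: probe grids differ, first mismatch at position {where}")
        num = numerator.values(chrom) + pseudocount
        den = denominator.values(chrom) + pseudocount
        if np.any(den <= 0):
            raise ValueError(f"{chrom}: denominator + pseudocount must be > 0 everywhere")
        if np.any(num <= 0):
            raise ValueError(f"{chrom}: numerator + pseudocount must be > 0 everywhere")
        new[chrom] = np.log2(num / den)
    return numerator.with_values(
        new, name=name or f"log2({numerator.name}/{denominator.name})", kind="log2_ratio"
    )


def smooth_probes(track: ProbeTrack, window_probes: int) -> ProbeTrack:
    """Centered moving mean over probe indices; edges shrink the window.

    Even windows are promoted to the next odd size (with a warning) so
    the window is always centered on its probe.
    """
    if window_probes < 1:
        raise ValueError("window must be >= 1 probe")
    if window_probes % 2 == 0:
        warnings.warn(
            f"even smoothing window {window_probes} promoted to {window_probes + 1}",
            stacklevel=2,
        )
        window_probes += 1
    new = {}
    for chrom in track.chroms():
        v = pd.Series(track.values(chrom))
        new[chrom] = v.rolling(window_probes, center=True, min_periods=1).mean().to_numpy()
    return track.with_values(new, name=f"{track.name}|smooth{window_probes}p")


def smooth_bp(track: ProbeTrack, window_bp: float) -> ProbeTrack:
    """Mean over probes within ``[pos - w/2, pos + w/2)`` of each probe."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2.0
    new = {}
    for chrom in track.chroms():
        pos = track.positions(chrom)
        val = track.values(chrom)
        csum = np.concatenate([[0.0], np.cumsum(val)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="left")
        cnt = hi - lo  # each probe is inside its own window, so cnt >= 1
        new[chrom] = (csum[hi] - csum[lo]) / cnt
    return track.with_values(new, name=f"{track.name}|smooth{window_bp:g}bp")
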