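"""Readers/writers for the interchange formats.

bedGraph carries probe tracks (one 1-bp interval per probe, probe
position = interval start), BED3/BED6 carries site lists and zone sets,
UCSC refFlat carries gene annotation, and a small whitespace-delimited
dense-matrix dialect with a ``bin_bp=<int> chrom=<name>`` header line
carries Hi-C style contact matrices.  Everything is plain text and
round-trips bit-compatibly through these functions.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    ZONE_COLUMNS,
    empty_genes,
    empty_sites,
    empty_zones,
    make_genes,
)
from .tracks import ProbeTrack

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_refflat",
    "write_refflat",
    "read_bed_sites",
    "write_bed_sites",
    "read_bed_zones",
    "write_bed_zones",
    "read_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """Malformed record in an input file (carries path and line number)."""


# ---------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------

def read_bedgraph(path, name: str | None = None, kind: str = "log2_ratio") -> ProbeTrack:
    """Read a 4-column bedGraph into a :class:`ProbeTrack`.

    Probes are points at the interval start.  Unsorted input is sorted
    with a warning; overlapping probe intervals are an error.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if s >= e:
                raise ParseError(f"{path}:{lineno}: start {s} >= end {e}")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            vals.append(v)

    track = ProbeTrack(name=name or path.stem, kind=kind)
    if not chroms:
        return track
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": vals})
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        val = sub["value"].to_numpy(float)
        if pos.size > 1 and np.any(np.diff(pos) < 0):
            warnings.warn(f"{path}: {chrom} not sorted; sorting", stacklevel=2)
            order = np.argsort(pos, kind="mergesort")
            pos, end, val = pos[order], end[order], val[order]
        if pos.size > 1 and np.any(end[:-1] > pos[1:]):
            i = int(np.flatnonzero(end[:-1] > pos[1:])[0])
            raise ParseError(
                f"{path}: overlapping probes on {chrom} near position {int(pos[i])}"
            )
        track.add_chromosome(chrom, pos, val)
    return track


def write_bedgraph(track: ProbeTrack, path) -> None:
    """Write each probe as a ``[pos, pos+1)`` interval with full float precision."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms()):
            pos = track.positions(chrom)
            val = track.values(chrom)
            df = pd.DataFrame({0: chrom, 1: pos, 2: pos + 1, 3: val})
            # pandas emits shortest round-trip float repr by default
            df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------
# refFlat
# ---------------------------------------------------------------------

def read_refflat(path) -> pd.DataFrame:
    """Read an 11-column UCSC refFlat table into a gene frame.

    TSS is ``txStart`` for '+' genes and ``txEnd - 1`` for '-' genes
    (0-based coordinates).
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ParseError(f"{path}:{lineno}: expected 11 tab-separated columns, "
                                 f"got {len(fields)}")
            strand = fields[3]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(
                {
                    "name": fields[0],
                    "chrom": fields[2],
                    "strand": strand,
                    "tx_start": tx_start,
                    "tx_end": tx_end,
                }
            )
    if not records:
        return empty_genes()
    return make_genes(records)


def write_refflat(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            s, e = int(g["tx_start"]), int(g["tx_end"])
            fh.write(
                "\t".join(
                    [
                        str(g["name"]), str(g["name"]), str(g["chrom"]), str(g["strand"]),
                        str(s), str(e), str(s), str(e), "1", f"{s},", f"{e},",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------

def read_bed_sites(path) -> pd.DataFrame:
    """BED3 of 1-bp (or wider) features -> point sites at interval start."""
    path = Path(path)
    chroms, positions = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chroms.append(fields[0])
            positions.append(int(fields[1]))
    if not chroms:
        return empty_sites()
    df = pd.DataFrame({"chrom": chroms, "pos": np.asarray(positions, dtype=np.int64)})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bed_sites(sites: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, s in sites.iterrows():
            fh.write(f"{s['chrom']}\t{int(s['pos'])}\t{int(s['pos']) + 1}\n")


def read_bed_zones(path, label: str | None = None) -> pd.DataFrame:
    """BED6 -> zone frame.  The BED name column becomes the label; the score
    column is decoded back to a mean score (score = 1000 * clamped score)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            records.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "n_probes": 0,
                    "mean_score": float(fields[4]) / 1000.0 if len(fields) >= 5 else np.nan,
                    "label": fields[3] if len(fields) >= 4 else (label or "zone"),
                }
            )
    if not records:
        return empty_zones()
    df = pd.DataFrame.from_records(records, columns=ZONE_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed_zones(zones: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, z in zones.iterrows():
            score = z["mean_score"]
            score = 0.0 if not np.isfinite(score) else min(max(score, 0.0), 1.0)
            fh.write(
                f"{z['chrom']}\t{int(z['start'])}\t{int(z['end'])}\t{z['label']}\t"
                f"{int(round(1000 * score))}\t.\n"
            )


def write_zone_table(zones: pd.DataFrame, path) -> None:
    """TSV companion of the BED6 output, keeping n_probes and mean_score exact."""
    zones.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# dense matrices
# ---------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, bin_bp: int, chrom: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"bin_bp={int(bin_bp)} chrom={chrom}\n")
        np.savetxt(fh, np.asarray(matrix, dtype=float))


def read_matrix(path) -> tuple[np.ndarray, int, str]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        try:
            kv = dict(item.split("=", 1) for item in header.split())
            bin_bp = int(kv["bin_bp"])
            chrom = kv["chrom"]
        except (ValueError, KeyError):
            raise ParseError(f"{path}:1: expected header 'bin_bp=<int> chrom=<name>'") from None
        matrix = np.loadtxt(fh, ndmin=2)
    return matrix, bin_bp, chrom
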