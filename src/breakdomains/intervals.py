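"""Shared genomic-interval containers.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Zones (enriched domains, cohesin peaks, depleted holes), point site
lists and gene tables are carried as plain :class:`pandas.DataFrame`
objects with fixed column schemas, which keeps them trivially
serializable to BED / refFlat and easy to manipulate with the usual
dataframe tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: columns of a zone set (domains, peaks, holes)
ZONE_COLUMNS = ["chrom", "start", "end", "n_probes", "mean_score", "label"]

#: columns of a point-site list (DSB positions, random draws)
SITE_COLUMNS = ["chrom", "pos"]

#: columns of a gene table (refFlat-derived)
GENE_COLUMNS = ["name", "chrom", "strand", "tx_start", "tx_end", "tss"]

#: columns of a boundary table
BOUNDARY_COLUMNS = ["chrom", "pos", "side", "zone_id"]


def empty_zones() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "n_probes": pd.Series(dtype=np.int64),
            "mean_score": pd.Series(dtype=float),
            "label": pd.Series(dtype=str),
        }
    )


def make_zones(records: list[dict]) -> pd.DataFrame:
    """Build a zone frame from dict records, sorted by (chrom, start)."""
    if not records:
        return empty_zones()
    df = pd.DataFrame.from_records(records, columns=ZONE_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["n_probes"] = df["n_probes"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"zone with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def empty_sites() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})


def make_sites(chroms, positions) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": list(chroms), "pos": np.asarray(positions, dtype=np.int64)})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def empty_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "strand": pd.Series(dtype=str),
            "tx_start": pd.Series(dtype=np.int64),
            "tx_end": pd.Series(dtype=np.int64),
            "tss": pd.Series(dtype=np.int64),
        }
    )


def tss_of(tx_start: int, tx_end: int, strand: str) -> int:
    """Transcription start: ``tx_start`` on '+', ``tx_end - 1`` on '-' (0-based)."""
    if strand == "+":
        return int(tx_start)
    if strand == "-":
        return int(tx_end) - 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def make_genes(records: list[dict]) -> pd.DataFrame:
    if not records:
        return empty_genes()
    df = pd.DataFrame.from_records(records)
    if "tss" not in df.columns:
        df["tss"] = [
            tss_of(s, e, st) for s, e, st in zip(df["tx_start"], df["tx_end"], df["strand"])
        ]
    df = df[GENE_COLUMNS].copy()
    df["tx_start"] = df["tx_start"].astype(np.int64)
    df["tx_end"] = df["tx_end"].astype(np.int64)
    df["tss"] = df["tss"].astype(np.int64)
    return df.sort_values(["chrom", "tx_start"], kind="mergesort").reset_index(drop=True)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of sorted-by-start intervals on one chromosome."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)
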