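"""Recovery metrics: called zones versus ground truth.

Used to score the caller on synthetic fixtures where the implanted
domains and holes are known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["boundary_errors", "mean_best_jaccard"]


def boundary_errors(true_zones: pd.DataFrame, called_zones: pd.DataFrame,
                    min_true_bp: int = 0) -> pd.DataFrame:
    """Per true zone: absolute start/end errors of the best-overlapping call.

    The best call is the one with the largest bp overlap; zones without
    any overlapping call get infinite errors.  ``min_true_bp`` restricts
    scoring to true zones of at least that width.
    """
    rows = []
    for _, t in true_zones.iterrows():
        width = int(t["end"] - t["start"])
        if width < min_true_bp:
            continue
        cand = called_zones[
            (called_zones["chrom"] == t["chrom"])
            & (called_zones["start"] < t["end"])
            & (called_zones["end"] > t["start"])
        ]
        if cand.empty:
            rows.append({"chrom": t["chrom"], "true_start": int(t["start"]),
                         "true_end": int(t["end"]), "start_error": np.inf,
                         "end_error": np.inf})
            continue
        overlap = np.minimum(cand["end"], t["end"]) - np.maximum(cand["start"], t["start"])
        best = cand.iloc[int(np.argmax(overlap.to_numpy()))]
        rows.append({
            "chrom": t["chrom"],
            "true_start": int(t["start"]),
            "true_end": int(t["end"]),
            "start_error": abs(int(best["start"]) - int(t["start"])),
            "end_error": abs(int(best["end"]) - int(t["end"])),
        })
    return pd.DataFrame(rows)


def mean_best_jaccard(true_zones: pd.DataFrame, called_zones: pd.DataFrame,
                      min_true_bp: int = 0) -> float:
    """Mean over true zones of the best Jaccard index with any call."""
    scores = []
    for _, t in true_zones.iterrows():
        if int(t["end"] - t["start"]) < min_true_bp:
            continue
        cand = called_zones[
            (called_zones["chrom"] == t["chrom"])
            & (called_zones["start"] < t["end"])
            & (called_zones["end"] > t["start"])
        ]
        best = 0.0
        for _, c in cand.iterrows():
            inter = min(c["end"], t["end"]) - max(c["start"], t["start"])
            union = (c["end"] - c["start"]) + (t["end"] - t["start"]) - inter
            best = max(best, inter / union)
        scores.append(best)
    return float(np.mean(scores)) if scores else float("nan")
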