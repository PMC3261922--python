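"""Break-site and gene-level statistics.

Window means at sites, paired t-tests between conditions, a
random-site permutation null, per-gene signal summaries, Pearson
correlation of cohesin occupancy against gamma-H2AX change, stratified
comparisons, one-sample expression-ratio tests and peak-set overlap
fractions.  All p-values are two-sided and reported raw (no
multiple-testing correction); a paired design whose differences are all
exactly zero reports p = 1 (the null is literally exact), while a
zero-variance design with a nonzero mean difference raises
:class:`DegenerateTestError`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import GenomeModel
from .tracks import ProbeTrack

__all__ = [
    "TestResult",
    "SimulationReport",
    "DegenerateTestError",
    "window_mean_at_sites",
    "paired_site_test",
    "random_site_null",
    "gene_signal",
    "signal_ratio_correlation",
    "tss_window_test",
    "stratified_compare",
    "expression_change_test",
    "peak_overlap_fraction",
]

logger = logging.getLogger(__name__)


class DegenerateTestError(ValueError):
    """Zero-variance design with a nonzero effect: t is undefined."""


@dataclass
class TestResult:
    """A t-test outcome: statistic, degrees of freedom, two-sided p, n."""

    t: float
    df: int
    p: float
    n: int
    mean_diff: float = math.nan

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class SimulationReport:
    """Outcome of the random-site null simulation."""

    p_values: np.ndarray
    n_sets: int
    sites_per_set: int
    window_bp: float
    seed: int
    alpha: float = 0.05
    fraction_below_alpha: float = field(init=False)
    log10_p_quartiles: tuple[float, float, float] = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.p_values, dtype=float)
        if p.size != self.n_sets:
            raise ValueError("one p-value per simulated set expected")
        self.fraction_below_alpha = float(np.mean(p < self.alpha))
        q = np.quantile(np.log10(np.maximum(p, np.finfo(float).tiny)), [0.25, 0.5, 0.75])
        self.log10_p_quartiles = (float(q[0]), float(q[1]), float(q[2]))


# ---------------------------------------------------------------------
# windows and means
# ---------------------------------------------------------------------

def window_mean_at_sites(track: ProbeTrack, sites: pd.DataFrame,
                         window_bp: float) -> pd.DataFrame:
    """Mean probe value within ``|pos - site| <= window_bp / 2`` (closed).

    Returns one row per site (``site_id, chrom, pos, n_probes, mean``);
    sites with no probes get ``n_probes = 0`` and NaN mean and are
    excluded by downstream tests (with a log entry).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2.0
    rows = []
    for site_id, (_, s) in enumerate(sites.iterrows()):
        chrom, p = str(s["chrom"]), int(s["pos"])
        if chrom not in track.chroms():
            rows.append((site_id, chrom, p, 0, np.nan))
            continue
        pos = track.positions(chrom)
        val = track.values(chrom)
        lo = np.searchsorted(pos, p - half, side="left")
        hi = np.searchsorted(pos, p + half, side="right")
        if hi > lo:
            rows.append((site_id, chrom, p, int(hi - lo), float(val[lo:hi].mean())))
        else:
            rows.append((site_id, chrom, p, 0, np.nan))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "n_probes", "mean"])


def _paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired test needs >= 2 pairs")
    if np.all(d == 0):
        return TestResult(t=0.0, df=n - 1, p=1.0, n=n, mean_diff=0.0)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError(
            "all paired differences identical but nonzero; t is undefined"
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(t=float(t), df=n - 1, p=float(min(p, 1.0)), n=n,
                      mean_diff=float(d.mean()))


def paired_site_test(track_a: ProbeTrack, track_b: ProbeTrack, sites: pd.DataFrame,
                     window_bp: float) -> TestResult:
    """Paired t-test of per-site window means between two tracks.

    Pairs are matched by site; sites lacking probes in either track are
    dropped (count logged).
    """
    ma = window_mean_at_sites(track_a, sites, window_bp)
    mb = window_mean_at_sites(track_b, sites, window_bp)
    ok = (ma["n_probes"] > 0) & (mb["n_probes"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("paired_site_test: dropped %d site(s) without probe coverage", n_dropped)
    a = ma.loc[ok, "mean"].to_numpy()
    b = mb.loc[ok, "mean"].to_numpy()
    return _paired_t(a, b)


def random_site_null(track_a: ProbeTrack, track_b: ProbeTrack, genome: GenomeModel,
                     n_sets: int, sites_per_set: int, window_bp: float,
                     seed: int, alpha: float = 0.05) -> SimulationReport:
    """Permutation null: paired site tests on uniformly drawn site sets.

    Each set draws ``sites_per_set`` positions uniformly over the
    genome (chromosomes weighted by length) and runs
    :func:`paired_site_test`; the report gathers the per-set p-values.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths()
    names = list(lengths)
    sizes = np.array([lengths[c] for c in names], dtype=float)
    weights = sizes / sizes.sum()
    p_values = np.empty(n_sets)
    for k in range(n_sets):
        chrom_idx = rng.choice(len(names), size=sites_per_set, p=weights)
        positions = (rng.random(sites_per_set) * sizes[chrom_idx]).astype(np.int64)
        sites = pd.DataFrame({"chrom": [names[i] for i in chrom_idx], "pos": positions})
        p_values[k] = paired_site_test(track_a, track_b, sites, window_bp).p
    return SimulationReport(p_values=p_values, n_sets=n_sets,
                            sites_per_set=sites_per_set, window_bp=window_bp,
                            seed=seed, alpha=alpha)


# ---------------------------------------------------------------------
# gene-level summaries
# ---------------------------------------------------------------------

def gene_signal(track: ProbeTrack, genes: pd.DataFrame) -> pd.Series:
    """Mean probe value over each gene body ``[tx_start, tx_end)``.

    Genes without probes get NaN (their count is logged).
    """
    out = np.full(len(genes), np.nan)
    n_empty = 0
    for k, (_, g) in enumerate(genes.iterrows()):
        chrom = str(g["chrom"])
        if chrom not in track.chroms():
            n_empty += 1
            continue
        pos = track.positions(chrom)
        val = track.values(chrom)
        i = np.searchsorted(pos, g["tx_start"], side="left")
        j = np.searchsorted(pos, g["tx_end"], side="left")
        if j > i:
            out[k] = val[i:j].mean()
        else:
            n_empty += 1
    if n_empty:
        logger.info("gene_signal: %d gene(s) without probe coverage", n_empty)
    return pd.Series(out, index=genes["name"].to_numpy(), name=track.name)


def signal_ratio_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-transform p (df = n - 2).

    NaN pairs are dropped; needs at least 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 finite pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise DegenerateTestError("zero variance in x or y; correlation undefined")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0)), n


def _oriented_window_mean(track: ProbeTrack, genes: pd.DataFrame,
                          lo_bp: float, hi_bp: float) -> np.ndarray:
    """Per-gene mean in the strand-oriented offset window [lo, hi) around TSS."""
    out = np.full(len(genes), np.nan)
    for k, (_, g) in enumerate(genes.iterrows()):
        chrom = str(g["chrom"])
        if chrom not in track.chroms():
            continue
        pos = track.positions(chrom)
        val = track.values(chrom)
        tss = int(g["tss"])
        if g["strand"] == "+":
            # offset = pos - tss in [lo, hi)
            i = np.searchsorted(pos, tss + lo_bp, side="left")
            j = np.searchsorted(pos, tss + hi_bp, side="left")
        else:
            # offset = tss - pos in [lo, hi)  ->  pos in (tss - hi, tss - lo]
            i = np.searchsorted(pos, tss - hi_bp, side="right")
            j = np.searchsorted(pos, tss - lo_bp, side="right")
        if j > i:
            out[k] = val[i:j].mean()
    return out


def tss_window_test(track_a: ProbeTrack, track_b: ProbeTrack, genes: pd.DataFrame,
                    offset_window: tuple[float, float]) -> TestResult:
    """Paired t-test across genes of the mean signal in a strand-oriented
    window relative to the TSS (e.g. the promoter window (-200, +200))."""
    lo_bp, hi_bp = offset_window
    if hi_bp <= lo_bp:
        raise ValueError("offset window must have lo < hi")
    a = _oriented_window_mean(track_a, genes, lo_bp, hi_bp)
    b = _oriented_window_mean(track_b, genes, lo_bp, hi_bp)
    ok = np.isfinite(a) & np.isfinite(b)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("tss_window_test: dropped %d gene(s) without probe coverage", n_dropped)
    return _paired_t(a[ok], b[ok])


def stratified_compare(ratio, covariate, low_cut: float, high_cut: float
                       ) -> dict:
    """Compare a covariate between genes with low (< low_cut) and high
    (> high_cut) ratio, by Welch two-sample t-test."""
    ratio = np.asarray(ratio, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = np.isfinite(ratio) & np.isfinite(covariate)
    ratio, covariate = ratio[ok], covariate[ok]
    low = covariate[ratio < low_cut]
    high = covariate[ratio > high_cut]
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"empty comparison group (low n={low.size}, high n={high.size})"
        )
    t, p = sps.ttest_ind(high, low, equal_var=False)
    return {
        "low_n": int(low.size),
        "high_n": int(high.size),
        "low_mean": float(low.mean()),
        "high_mean": float(high.mean()),
        "t": float(t),
        "p": float(p),
    }


def expression_change_test(fold_changes: np.ndarray,
                           gene_names=None, null_ratio: float = 1.0) -> pd.DataFrame:
    """One-sample t-test per gene of replicate fold changes against a
    theoretical ratio of 1 (no change after break induction).

    ``fold_changes`` is (n_genes, n_replicates).  Returns one row per
    gene with t, df, p and the mean fold change.
    """
    fc = np.atleast_2d(np.asarray(fold_changes, dtype=float))
    n_genes, n_rep = fc.shape
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per gene")
    rows = []
    for g in range(n_genes):
        d = fc[g] - null_ratio
        if np.all(d == 0):
            res = TestResult(t=0.0, df=n_rep - 1, p=1.0, n=n_rep, mean_diff=0.0)
        else:
            sd = d.std(ddof=1)
            if sd == 0:
                raise DegenerateTestError(
                    f"gene {g}: identical nonzero deviations; t is undefined"
                )
            t = d.mean() / (sd / math.sqrt(n_rep))
            res = TestResult(t=float(t), df=n_rep - 1,
                             p=float(min(2.0 * sps.t.sf(abs(t), n_rep - 1), 1.0)),
                             n=n_rep, mean_diff=float(d.mean()))
        rows.append(
            {
                "gene": gene_names[g] if gene_names is not None else g,
                "mean_fold_change": float(fc[g].mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def peak_overlap_fraction(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Fraction of zones in A that overlap (>= 1 bp) at least one zone in B."""
    if set_a.empty:
        raise ValueError("set_a is empty; overlap fraction undefined")
    if set_b.empty:
        return 0.0
    n_hit = 0
    for chrom, sub_a in set_a.groupby("chrom"):
        sub_b = set_b[set_b["chrom"] == chrom].sort_values("start")
        if sub_b.empty:
            continue
        b_starts = sub_b["start"].to_numpy()
        b_ends = np.maximum.accumulate(sub_b["end"].to_numpy())
        for _, z in sub_a.iterrows():
            # first b whose running max end exceeds z.start
            i = np.searchsorted(b_ends, z["start"], side="right")
            if i < b_starts.size and b_starts[i] < z["end"]:
                n_hit += 1
    return n_hit / len(set_a)
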