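"""Exhaustive pure-Python reference implementation of the zone caller.

Deliberately naive and fully independent of :mod:`breakdomains.caller`:
every seed window is enumerated with an explicit count, edge extension
is simulated probe-by-probe on Python lists, and merge/filter work on
plain tuples.  It exists solely as a validation oracle — the test suite
and the acceptance script check that the vectorized caller reproduces
it exactly on random tracks.
"""

import math


def oracle_percentile(values, pct):
    s = sorted(float(v) for v in values)
    rank = math.ceil(pct / 100.0 * len(s))
    return s[rank - 1]


def oracle_seed_zones(values, threshold, n_seed, min_above):
    n = len(values)
    covered = [False] * n
    for i in range(n - n_seed + 1):
        count = sum(1 for v in values[i:i + n_seed] if v > threshold)
        if count >= min_above:
            for k in range(i, i + n_seed):
                covered[k] = True
    zones = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            zones.append((i, j))
            i = j
        else:
            i += 1
    return zones


def oracle_extend(values, threshold, zone, ext_window, ext_fraction, lo, hi):
    above = [v > threshold for v in values]
    start, end = zone
    j = start - 1
    while j >= lo:
        win = above[j:min(j + ext_window, hi)]
        if sum(win) > ext_fraction * len(win):
            j -= 1
        else:
            break
    start = j + 1
    j = end
    while j < hi:
        win = above[max(j - ext_window + 1, lo):j + 1]
        if sum(win) > ext_fraction * len(win):
            j += 1
        else:
            break
    end = j
    return start, end


def oracle_call(positions, values, params):
    """Full composed caller; returns (start, end, n_probes, mean_score) tuples."""
    positions = [int(p) for p in positions]
    values = [float(v) for v in values]
    n = len(values)
    if n == 0:
        return []
    T = oracle_percentile(values, params.threshold_percentile)
    seeds = oracle_seed_zones(values, T, params.n_seed, params.min_above)
    ew = params.effective_ext_window
    ef = params.effective_ext_fraction
    zones = []
    for k, seed in enumerate(seeds):
        lo = seeds[k - 1][1] if k > 0 else 0
        hi = seeds[k + 1][0] if k + 1 < len(seeds) else n
        i, j = oracle_extend(values, T, seed, ew, ef, lo, hi)
        zones.append((positions[i], positions[j - 1] + 1))
    # merge
    merged = []
    for s, e in sorted(zones):
        if merged and (s - merged[-1][1] < params.merge_gap_bp or s < merged[-1][1]):
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    # rescore over every probe within each merged span, then filter
    out = []
    for s, e in merged:
        member = [v for p, v in zip(positions, values) if s <= p < e]
        n_probes = len(member)
        mean_score = sum(member) / n_probes if n_probes else float("nan")
        if (n_probes >= params.min_probes and (e - s) >= params.min_bp
                and mean_score >= params.min_mean_score):
            out.append((s, e, n_probes, mean_score))
    return out


def random_case(rng, max_probes=500):
    """A random track + random caller parameters for equivalence testing."""
    from breakdomains.caller import CallerParams

    n = int(rng.integers(30, max_probes + 1))
    spacing = int(rng.integers(1, 60))
    positions = [k * spacing for k in range(n)]
    values = rng.normal(0.0, 1.0, size=n)
    # implant 0-3 enriched blocks so zones actually occur
    for _ in range(int(rng.integers(0, 4))):
        width = int(rng.integers(5, max(6, n // 3)))
        start = int(rng.integers(0, n - width))
        values[start:start + width] += rng.uniform(1.0, 4.0)
    n_seed = int(rng.integers(3, 26))
    min_above = int(rng.integers(1, n_seed + 1))
    params = CallerParams(
        n_seed=n_seed,
        min_above=min_above,
        threshold_percentile=float(rng.uniform(40, 95)),
        ext_window=int(rng.integers(1, 26)) if rng.random() < 0.5 else None,
        ext_fraction=float(rng.uniform(0, 1)) if rng.random() < 0.5 else None,
        merge_gap_bp=int(rng.integers(0, 5 * spacing + 1)),
        min_probes=int(rng.integers(0, 10)),
        min_bp=int(rng.integers(0, 10 * spacing + 1)),
        min_mean_score=float(rng.uniform(-2, 0.5)) if rng.random() < 0.3 else -math.inf,
    )
    return positions, values, params
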