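"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: Fisher p-values
come from explicit hypergeometric enumeration with exact integer
combinatorics, ROH and CNV segmentation from from-scratch window checks, and
shared-homozygosity intervals from per-basepair counting.
"""

from __future__ import annotations

from itertools import groupby
from math import comb

import numpy as np

from cscm_sieve.association import ROHParams, ROHRun, SharedInterval
from cscm_sieve.core import HET, MISSING


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct enumeration of all tables with the
    observed margins, using exact integer combinatorics."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = comb(r1, k) * comb(r2, c1 - k) / denom
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def roh_scan_bruteforce(
    positions: list[int], gts: list[int], params: ROHParams, sample: str = "s", chrom: str = "chr1"
) -> list[ROHRun]:
    """From-scratch ROH scan: at each candidate start, grow the window while a
    full recount of its constraints passes, close at the last homozygous
    site, then resume after it."""
    sites = [(p, g) for p, g in zip(positions, gts) if g != MISSING]
    sites.sort()

    def window_ok(i: int, j: int) -> bool:
        hets = sum(1 for _, g in sites[i : j + 1] if g == HET)
        if hets > params.max_het:
            return False
        for (p0, _), (p1, _) in zip(sites[i:j], sites[i + 1 : j + 1]):
            if p1 - p0 > params.max_gap_kb * 1000:
                return False
        return True

    runs = []
    i = 0
    n = len(sites)
    while i < n:
        if sites[i][1] == HET:
            i += 1
            continue
        j = i
        while j + 1 < n and window_ok(i, j + 1):
            j += 1
        last_hom = max(k for k in range(i, j + 1) if sites[k][1] != HET)
        n_snps = last_hom - i + 1
        length = sites[last_hom][0] - sites[i][0] + 1
        if n_snps >= params.min_snps and length >= params.min_kb * 1000:
            n_het = sum(1 for k in range(i, last_hom + 1) if sites[k][1] == HET)
            runs.append(ROHRun(sample, chrom, sites[i][0], sites[last_hom][0], n_snps, n_het))
        i = max(last_hom + 1, i + 1)
    return runs


def segment_runs_bruteforce(
    ratios: list[float], loss_max: float, gain_min: float, min_windows: int
) -> list[tuple[int, int, str]]:
    """Per-window state labels grouped into runs: (start_idx, end_idx, state)."""
    states = [
        "loss" if r < loss_max else "gain" if r > gain_min else "normal" for r in ratios
    ]
    out = []
    i = 0
    for state, grp in groupby(states):
        width = len(list(grp))
        if state != "normal" and width >= min_windows:
            out.append((i, i + width - 1, state))
        i += width
    return out


def shared_intervals_per_bp(
    roh_sets: dict[str, list[ROHRun]], chrom: str, chrom_len: int, min_cases: int
) -> list[SharedInterval]:
    """Shared-homozygosity intervals by counting coverage at every basepair."""
    depth = np.zeros(chrom_len + 2, dtype=np.int32)
    for runs in roh_sets.values():
        covered = np.zeros(chrom_len + 2, dtype=bool)
        for r in runs:
            if r.chrom == chrom:
                covered[r.start : r.end + 1] = True
        depth += covered
    out = []
    start = None
    for pos in range(1, chrom_len + 2):
        d = int(depth[pos]) if pos <= chrom_len else 0
        if d >= min_cases and start is None:
            start, cur = pos, d
        elif start is not None and d != cur:
            out.append(SharedInterval(chrom, start, pos - 1, cur))
            start, cur = (pos, d) if d >= min_cases else (None, None)
    return out
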