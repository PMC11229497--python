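"""Sequence-based case/control association and homozygosity analysis.

The association test is a two-sided Fisher exact test on per-site 2x2 allele
count tables, exact at the small case counts a rare-disease series implies
(PLINK's default allelic chi-square is asymptotic).  Control cohorts are
pruned for relatedness with a method-of-moments identity-by-descent
estimator (PI-HAT analog) before testing; genome-wide significance uses the
Bonferroni bound alpha / n_tests.

Runs of homozygosity (ROH) are found with a consecutive-runs scanner in the
style of detectRUNS, and regions of homozygosity shared across cases are
extracted with a breakpoint sweep over the per-case ROH intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import HET, MISSING, CohortGenotypes

# ---------------------------------------------------------------------------
# Fisher exact association


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(
    k_obs: np.ndarray, K: np.ndarray, n_alt: np.ndarray, M: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for allele-count tables.

    Site-wise hypergeometric model: ``M`` total alleles of which ``n_alt``
    are alternate; ``K`` alleles belong to cases; ``k_obs`` alternate alleles
    observed in cases.  Two-sided p sums the probabilities of all tables (with
    the same margins) no more probable than the observed one, matching the
    scipy convention with a (1 + 1e-7) relative tolerance for ties.
    """
    k_obs = np.atleast_1d(np.asarray(k_obs, dtype=np.int64))
    K = np.broadcast_to(np.asarray(K, dtype=np.int64), k_obs.shape)
    n_alt = np.broadcast_to(np.asarray(n_alt, dtype=np.int64), k_obs.shape)
    M = np.broadcast_to(np.asarray(M, dtype=np.int64), k_obs.shape)
    lo = np.maximum(0, n_alt - (M - K))
    hi = np.minimum(K, n_alt)
    width = int((hi - lo).max()) + 1 if k_obs.size else 1
    grid = lo[:, None] + np.arange(width)[None, :]
    valid = grid <= hi[:, None]
    g = np.where(valid, grid, 0)
    logpmf = (
        _log_comb(K[:, None], g)
        + _log_comb((M - K)[:, None], n_alt[:, None] - g)
        - _log_comb(M, n_alt)[:, None]
    )
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    obs = np.take_along_axis(pmf, (k_obs - lo)[:, None], axis=1)
    p = (pmf * (pmf <= obs * (1 + 1e-7))).sum(axis=1)
    return np.minimum(p, 1.0)


def allelic_association(
    cohort: CohortGenotypes, case_ids: list[str], control_ids: list[str]
) -> pd.DataFrame:
    """Two-sided Fisher exact test on allele counts at every biallelic site.

    Missing genotypes are dropped per site.  Sites with no informative
    genotypes get p = NaN and ``informative`` False.
    """
    ci = cohort.sample_indices(case_ids)
    ki = cohort.sample_indices(control_ids)
    case_gt = cohort.gt[:, ci]
    ctrl_gt = cohort.gt[:, ki]

    def allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        called = gt != MISSING
        alt = np.where(called, gt, 0).sum(axis=1)
        total = 2 * called.sum(axis=1)
        return alt.astype(np.int64), total.astype(np.int64)

    case_alt, case_tot = allele_counts(case_gt)
    ctrl_alt, ctrl_tot = allele_counts(ctrl_gt)
    M = case_tot + ctrl_tot
    n_alt = case_alt + ctrl_alt
    informative = M > 0
    p = np.full(cohort.n_variants, np.nan)
    if informative.any():
        p[informative] = fisher_exact_two_sided(
            case_alt[informative], case_tot[informative], n_alt[informative], M[informative]
        )
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in cohort.variants],
            "pos": [v.pos for v in cohort.variants],
            "ref": [v.ref for v in cohort.variants],
            "alt": [v.alt for v in cohort.variants],
            "case_alt": case_alt,
            "case_ref": case_tot - case_alt,
            "control_alt": ctrl_alt,
            "control_ref": ctrl_tot - ctrl_alt,
            "p_value": p,
            "informative": informative,
        }
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# relatedness


def pairwise_relatedness(cohort: CohortGenotypes, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Method-of-moments IBD-proportion estimate (PI-HAT analog) per pair.

    Per-site allele frequencies give the expected identity-by-state (IBS)
    distribution under each IBD state; solving the moment equations yields
    P(IBD=1) and P(IBD=2), and PI-HAT = P(IBD=2) + P(IBD=1) / 2, clamped to
    [0, 1].  Monomorphic-only input is an error (frequencies undefined).
    """
    samples = sample_ids if sample_ids is not None else cohort.samples
    idx = cohort.sample_indices(samples)
    # allele frequencies from the whole cohort, not just the queried subset
    all_called = cohort.gt != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(all_called, cohort.gt, 0).sum(axis=1) / (
            2 * all_called.sum(axis=1).clip(min=1)
        )
    poly = (p > 0) & (p < 1) & (all_called.sum(axis=1) > 0)
    if not poly.any():
        raise ValueError("all sites monomorphic; allele frequencies undefined")
    p = p[poly]
    q = 1 - p
    gts = cohort.gt[:, idx][poly]
    # expected per-site IBS probabilities conditional on IBD state, summed later
    e_ibs0_ibd0 = 2 * p**2 * q**2
    e_ibs1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs2_ibd0 = 1 - e_ibs0_ibd0 - e_ibs1_ibd0
    e_ibs1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_ibd1 = 1 - e_ibs1_ibd1
    n = len(samples)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            g1, g2 = gts[:, i], gts[:, j]
            ok = (g1 != MISSING) & (g2 != MISSING)
            diff = np.abs(g1 - g2)
            ibs0 = float(np.sum(ok & (diff == 2)))
            ibs1 = float(np.sum(ok & (diff == 1)))
            ibs2 = float(np.sum(ok & (diff == 0)))
            s0 = float(e_ibs0_ibd0[ok].sum())
            s1_0 = float(e_ibs1_ibd0[ok].sum())
            s2_0 = float(e_ibs2_ibd0[ok].sum())
            s1_1 = float(e_ibs1_ibd1[ok].sum())
            s2_1 = float(e_ibs2_ibd1[ok].sum())
            n_ok = float(ok.sum())
            p0 = ibs0 / s0 if s0 > 0 else 0.0
            p1 = (ibs1 - p0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
            p2 = (ibs2 - p0 * s2_0 - p1 * s2_1) / n_ok if n_ok > 0 else 0.0
            pihat = min(max(p2 + 0.5 * p1, 0.0), 1.0)
            out[i, j] = out[j, i] = pihat
    return pd.DataFrame(out, index=samples, columns=samples)


def prune_related(matrix: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Greedily drop samples until no pair has relatedness >= threshold.

    At each step the sample participating in the most offending pairs is
    removed; ties broken by sample-id order.  Returns the retained samples
    in their original order.
    """
    samples = list(matrix.index)
    m = matrix.to_numpy().copy()
    np.fill_diagonal(m, 0.0)
    active = dict.fromkeys(samples)
    while True:
        idx = [samples.index(s) for s in active]
        sub = m[np.ix_(idx, idx)]
        offending = sub >= threshold
        if not offending.any():
            return list(active)
        counts = offending.sum(axis=1)
        order = sorted(range(len(idx)), key=lambda i: (-counts[i], list(active)[i]))
        del active[list(active)[order[0]]]


# ---------------------------------------------------------------------------
# runs of homozygosity


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 20
    min_kb: float = 500.0
    max_het: int = 1
    max_gap_kb: float = 250.0


@dataclass(frozen=True)
class ROHRun:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(
    cohort: CohortGenotypes, sample: str, params: ROHParams = ROHParams()
) -> list[ROHRun]:
    """Consecutive-runs scan for runs of homozygosity in one sample.

    A run starts and ends on a homozygous site, may contain at most
    ``max_het`` heterozygous sites, tolerates missing sites (skipped, not
    counted), and breaks when the gap between consecutive informative sites
    exceeds ``max_gap_kb``.  Emitted runs satisfy ``min_snps`` (informative
    sites in the run) and ``min_kb``.
    """
    gts = cohort.genotypes_of(sample)
    runs: list[ROHRun] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for v, g in zip(cohort.variants, gts):
        if g == MISSING:
            continue
        by_chrom.setdefault(v.chrom, []).append((v.pos, int(g)))
    max_gap = params.max_gap_kb * 1000
    for chrom, sites in by_chrom.items():
        sites.sort()
        pos = [s[0] for s in sites]
        het = [s[1] == HET for s in sites]
        n = len(sites)
        i = 0
        while i < n:
            if het[i]:
                i += 1
                continue
            hets = 0
            last_hom = i
            j = i + 1
            while j < n:
                if pos[j] - pos[j - 1] > max_gap:
                    break
                if het[j]:
                    if hets + 1 > params.max_het:
                        break
                    hets += 1
                else:
                    last_hom = j
                j += 1
            n_snps = last_hom - i + 1
            length = pos[last_hom] - pos[i] + 1
            n_het_used = sum(1 for k in range(i, last_hom + 1) if het[k])
            if n_snps >= params.min_snps and length >= params.min_kb * 1000:
                runs.append(ROHRun(sample, chrom, pos[i], pos[last_hom], n_snps, n_het_used))
            i = max(last_hom + 1, i + 1)
    runs.sort(key=lambda r: (r.chrom, r.start))
    return runs


@dataclass(frozen=True)
class SharedInterval:
    chrom: str
    start: int
    end: int
    n_cases: int


def shared_homozygosity(
    roh_sets: dict[str, list[ROHRun]], min_cases: int = 2
) -> list[SharedInterval]:
    """Breakpoint sweep for intervals homozygous in >= min_cases cases.

    Per-case ROH are unioned first so one case never counts twice.  The
    result is the list of constant-count intervals with count >= min_cases;
    adjacent intervals with equal count are merged, so each reported interval
    is maximal for its case count.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for case, runs in roh_sets.items():
        merged: dict[str, list[tuple[int, int]]] = {}
        for r in sorted(runs, key=lambda r: (r.chrom, r.start)):
            lst = merged.setdefault(r.chrom, [])
            if lst and r.start <= lst[-1][1] + 1:
                lst[-1] = (lst[-1][0], max(lst[-1][1], r.end))
            else:
                lst.append((r.start, r.end))
        for chrom, intervals in merged.items():
            ev = events.setdefault(chrom, [])
            for s, e in intervals:
                ev.append((s, 1))
                ev.append((e + 1, -1))
    out: list[SharedInterval] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        # coalesce events at the same position
        depth = 0
        pts: list[tuple[int, int]] = []
        for pos, delta in ev:
            if pts and pts[-1][0] == pos:
                pts[-1] = (pos, pts[-1][1] + delta)
            else:
                pts.append((pos, delta))
        for (pos, delta), nxt in zip(pts, pts[1:] + [(None, 0)]):
            depth += delta
            if nxt[0] is None:
                break
            if depth >= min_cases and nxt[0] > pos:
                if out and out[-1].chrom == chrom and out[-1].end == pos - 1 and out[-1].n_cases == depth:
                    out[-1] = SharedInterval(chrom, out[-1].start, nxt[0] - 1, depth)
                else:
                    out.append(SharedInterval(chrom, pos, nxt[0] - 1, depth))
    return out
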