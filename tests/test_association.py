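"""Fisher exact association, relatedness pruning and ROH detection."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from cscm_sieve.association import (
    ROHParams,
    ROHRun,
    allelic_association,
    bonferroni_threshold,
    detect_roh,
    fisher_exact_two_sided,
    pairwise_relatedness,
    prune_related,
    shared_homozygosity,
)
from cscm_sieve.core import HET, HOM_ALT, HOM_REF, MISSING
from cscm_sieve.synth import SimConfig, plant_shared_roh, simulate_cohort

from conftest import make_cohort
from oracles import fisher_p_enumeration, roh_scan_bruteforce, shared_intervals_per_bp


class TestFisher:
    def test_identical_allele_counts_give_p_one(self):
        gt = np.array([[HET, HET, HET, HET]], dtype=np.int8)
        cohort = make_cohort(gt)
        res = allelic_association(cohort, ["s0", "s1"], ["s2", "s3"])
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_sum(self):
        # cases 10 alt / 0 ref, controls 0 alt / 10 ref
        p = fisher_exact_two_sided(np.array([10]), np.array([10]), np.array([10]), np.array([20]))[0]
        assert p == pytest.approx(fisher_p_enumeration(10, 0, 0, 10), rel=1e-12)

    def test_enumeration_oracle_over_all_small_tables(self):
        """Exact agreement with direct hypergeometric enumeration on every
        2x2 table with all cells <= 7 plus random tables with margins <= 30."""
        for a in range(8):
            for b in range(8):
                for c in range(8):
                    for d in range(8):
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        got = fisher_exact_two_sided(
                            np.array([a]), np.array([a + b]), np.array([a + c]),
                            np.array([a + b + c + d]),
                        )[0]
                        assert got == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)
        rng = np.random.default_rng(4)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            got = fisher_exact_two_sided(
                np.array([a]), np.array([a + b]), np.array([a + c]), np.array([a + b + c + d])
            )[0]
            assert got == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)

    def test_label_permutation_leaves_null_p_distribution_unchanged(self):
        """Under the null, swapping case/control labels yields the same
        p-value distribution (two-sample KS p > 0.01 at 1,000 sites)."""
        rng = np.random.default_rng(8)
        n_sites = 1_000
        maf = rng.uniform(0.1, 0.5, n_sites)
        gt = rng.binomial(2, maf[:, None], (n_sites, 20)).astype(np.int8)
        cohort = make_cohort(gt, positions=list(range(1000, 1000 * (n_sites + 1), 1000)))
        samples = cohort.samples
        p1 = allelic_association(cohort, samples[:5], samples[5:])["p_value"]
        perm = list(rng.permutation(samples))
        p2 = allelic_association(cohort, perm[:5], perm[5:])["p_value"]
        assert ks_2samp(p1, p2).pvalue > 0.01

    def test_uninformative_site_flagged(self):
        gt = np.array([[MISSING, MISSING, MISSING, MISSING]], dtype=np.int8)
        cohort = make_cohort(gt)
        res = allelic_association(cohort, ["s0", "s1"], ["s2", "s3"])
        assert not res["informative"].iloc[0]
        assert np.isnan(res["p_value"].iloc[0])


@pytest.mark.parametrize(
    "alpha, n, expected",
    [(0.05, 15_625_000, 3.2e-9), (0.05, 1, 0.05), (0.01, 100, 1e-4)],
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.0, 10)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


@pytest.fixture(scope="module")
def rel_sim():
    return simulate_cohort(SimConfig(seed=3, n_background_variants=10_000))


class TestRelatedness:
    @pytest.fixture
    def sim(self, rel_sim):
        return rel_sim

    def test_self_relatedness_is_one(self, sim):
        rel = pairwise_relatedness(sim.cohort, ["case_1", "ctrl_00"])
        assert rel.loc["case_1", "case_1"] == 1.0

    def test_parent_offspring_near_half(self, sim):
        rel = pairwise_relatedness(sim.cohort, ["case_1", "sire_1", "dam_1"])
        assert 0.45 <= rel.loc["case_1", "sire_1"] <= 0.55
        assert 0.45 <= rel.loc["case_1", "dam_1"] <= 0.55

    def test_independent_samples_near_zero(self, sim):
        rel = pairwise_relatedness(sim.cohort, ["ctrl_00", "ctrl_01", "ctrl_02"])
        off = rel.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off <= 0.1)

    def test_monomorphic_only_input_raises(self):
        gt = np.zeros((50, 4), dtype=np.int8)
        cohort = make_cohort(gt)
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_relatedness(cohort)


class TestPruning:
    def _matrix(self, values, samples):
        import pandas as pd

        return pd.DataFrame(values, index=samples, columns=samples)

    def test_no_offending_pair_keeps_everyone(self):
        m = self._matrix(np.eye(3) + 0.1, ["a", "b", "c"])
        np.fill_diagonal(m.values, 1.0)
        assert prune_related(m) == ["a", "b", "c"]

    def test_duplicated_sample_drops_exactly_one(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 1.0
        kept = prune_related(self._matrix(m, ["a", "b", "c"]))
        assert kept == ["b", "c"]  # tie on counts, id order drops 'a'

    def test_related_triple_among_unrelated(self):
        n = 20
        samples = [f"s{i:02d}" for i in range(n)]
        m = np.eye(n)
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                if i != j:
                    m[i, j] = 0.6
        kept = prune_related(self._matrix(m, samples))
        assert set(samples[3:]).issubset(kept)
        assert len([s for s in kept if s in samples[:3]]) == 1


class TestROH:
    def test_all_het_sample_has_no_runs(self):
        gt = np.full((100, 1), HET, dtype=np.int8)
        cohort = make_cohort(gt, positions=list(range(10_000, 1_010_000, 10_000)))
        assert detect_roh(cohort, "s0") == []

    def test_planted_two_mb_stretch_recovered(self):
        """120 consecutive hom sites over 2 Mb: exactly one run covering the
        stretch within one inter-SNP spacing."""
        rng = np.random.default_rng(6)
        positions, gts = [], []
        pos = 100_000
        for i in range(400):
            pos += int(rng.integers(5_000, 25_000))
            positions.append(pos)
        start_i, end_i = 120, 239
        for i in range(400):
            if start_i <= i <= end_i:
                gts.append(HOM_ALT if rng.random() < 0.5 else HOM_REF)
            elif i in (start_i - 2, start_i - 1, end_i + 1, end_i + 2):
                gts.append(HET)  # bound the stretch so the truth edge is sharp
            else:
                gts.append(HET if rng.random() < 0.5 else HOM_REF)
        gt = np.array(gts, dtype=np.int8)[:, None]
        cohort = make_cohort(gt, positions=positions)
        params = ROHParams(min_snps=20, min_kb=500, max_het=1, max_gap_kb=250)
        runs = detect_roh(cohort, "s0", params)
        spacing = 25_000
        big = [r for r in runs if r.n_snps >= 100]
        assert len(big) == 1
        assert abs(big[0].start - positions[start_i]) <= spacing
        assert abs(big[0].end - positions[end_i]) <= spacing

    def test_run_split_by_exceeding_het_budget(self):
        positions = list(range(10_000, 10_000 * 125, 10_000))
        gts = [HOM_REF] * 60 + [HET, HET] + [HOM_REF] * 62
        cohort = make_cohort(np.array(gts, dtype=np.int8)[:, None], positions=positions)
        params = ROHParams(min_snps=20, min_kb=300, max_het=1, max_gap_kb=250)
        runs = detect_roh(cohort, "s0", params)
        assert len(runs) == 2
        assert runs[0].end < positions[60] and runs[1].start > positions[61]

    def test_scanner_equals_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(13)
        params = ROHParams(min_snps=5, min_kb=50, max_het=1, max_gap_kb=100)
        for rep in range(30):
            n = int(rng.integers(10, 200))
            positions = np.cumsum(rng.integers(1_000, 60_000, size=n)).tolist()
            gts = rng.choice(
                np.array([HOM_REF, HET, HOM_ALT, MISSING], dtype=np.int8),
                size=n, p=[0.5, 0.25, 0.2, 0.05],
            )
            cohort = make_cohort(gts[:, None], positions=positions)
            got = detect_roh(cohort, "s0", params)
            want = roh_scan_bruteforce(positions, list(gts), params, "s0", "chr1")
            assert [(r.start, r.end, r.n_snps) for r in got] == [
                (r.start, r.end, r.n_snps) for r in want
            ]


class TestSharedHomozygosity:
    def test_single_case_below_min_cases_is_empty(self):
        runs = {"c1": [ROHRun("c1", "chr1", 100, 5_000, 30, 0)]}
        assert shared_homozygosity(runs, min_cases=2) == []

    def test_identical_roh_in_all_cases(self):
        runs = {
            c: [ROHRun(c, "chr1", 1_000, 9_000, 30, 0)] for c in ("c1", "c2", "c3")
        }
        out = shared_homozygosity(runs, min_cases=2)
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].n_cases) == (1_000, 9_000, 3)

    def test_staggered_runs_match_per_bp_oracle(self):
        rng = np.random.default_rng(21)
        for rep in range(10):
            roh_sets = {}
            for c in range(4):
                runs = []
                pos = 1
                while pos < 900_000:
                    start = pos + int(rng.integers(0, 50_000))
                    end = start + int(rng.integers(10_000, 120_000))
                    if end > 1_000_000:
                        break
                    runs.append(ROHRun(f"c{c}", "chr1", start, end, 25, 0))
                    pos = end + int(rng.integers(1, 40_000))
                roh_sets[f"c{c}"] = runs
            got = shared_homozygosity(roh_sets, min_cases=2)
            want = shared_intervals_per_bp(roh_sets, "chr1", 1_000_000, 2)
            assert [(i.start, i.end, i.n_cases) for i in got] == [
                (i.start, i.end, i.n_cases) for i in want
            ]

    def test_planted_shared_stretch_detected_in_cohort(self, small_sim):
        rng = np.random.default_rng(5)
        cohort, _ = plant_shared_roh(
            small_sim.cohort, ["case_1", "case_2"], "chr1", 2_000_000, 4_000_000, rng
        )
        roh_sets = {c: detect_roh(cohort, c) for c in ("case_1", "case_2")}
        out = [i for i in shared_homozygosity(roh_sets, 2) if i.n_cases == 2]
        assert out, "planted shared stretch not found"
        assert out[0].start < 2_200_000 and out[-1].end > 3_800_000
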