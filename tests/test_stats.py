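import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import kstest

from msatpop import stats
from msatpop.synth import make_island_world
from msatpop.types import ValidationError
from .conftest import build_gm


class TestAlleleFrequencies:
    def test_two_homozygotes(self):
        gm = build_gm([[(100, 100)], [(104, 104)]])
        ft = stats.allele_frequencies(gm)
        assert ft.frequencies(0).tolist() == [[0.5, 0.5]]
        assert ft.gene_counts[0, 0] == 4

    def test_all_missing_cell_flagged(self):
        gm = build_gm(
            [[(100, 100)], [None]], populations=["A", "B"]
        )
        ft = stats.allele_frequencies(gm)
        assert ("B", 0) in ft.empty_cells()

    def test_frequencies_sum_to_one(self, island_world):
        gm, _ = island_world
        ft = stats.allele_frequencies(gm)
        for j in range(ft.n_loci):
            f = ft.frequencies(j)
            sums = np.nansum(f, axis=1)
            assert np.allclose(sums[~np.isnan(f).all(axis=1)], 1.0, atol=1e-12)

    def test_grouping_must_partition(self, island_world):
        gm, _ = island_world
        with pytest.raises(ValidationError):
            stats.allele_frequencies(gm, {"only_some": np.arange(3)})


class TestDiversityTable:
    def test_monomorphic_cell(self):
        gm = build_gm([[(100, 100)], [(100, 100)]])
        row = stats.diversity_table(gm).iloc[0]
        assert row.H_O == 0.0 and row.H_E == 0.0 and row.N_A == 1

    def test_unbiased_he_formula(self):
        # 10 individuals, two alleles at 0.5 -> (20/19) * 0.5 = 0.526315...
        gm = build_gm([[(100, 104)]] * 10)
        row = stats.diversity_table(gm).iloc[0]
        assert row.H_E == pytest.approx(20 / 19 * 0.5, abs=1e-12)
        assert row.H_O == 1.0

    def test_he_invariant_under_relabelling(self):
        g1 = build_gm([[(100, 104)], [(100, 100)], [(104, 104)]])
        g2 = build_gm([[(200, 300)], [(200, 200)], [(300, 300)]])
        assert stats.diversity_table(g1).iloc[0].H_E == pytest.approx(
            stats.diversity_table(g2).iloc[0].H_E
        )

    def test_au_fraction_of_singletons(self):
        # alleles 100 (3 copies), 104 (1 copy): A_U = 1/2
        gm = build_gm([[(100, 100)], [(100, 104)]])
        assert stats.diversity_table(gm).iloc[0].A_U == pytest.approx(0.5)

    def test_private_alleles(self):
        gm = build_gm(
            [[(100, 104)], [(100, 100)]], populations=["A", "B"]
        )
        df = stats.diversity_table(gm)
        a = df[df.population == "A"].iloc[0]
        b = df[df.population == "B"].iloc[0]
        assert a.private_alleles == 1 and b.private_alleles == 0


class TestRarefiedRichness:
    def test_monomorphic_is_one(self):
        gm = build_gm([[(100, 100)]] * 6)
        assert stats.rarefied_allelic_richness(gm, g=10).iloc[0].A_R == pytest.approx(1.0)

    def test_all_distinct_full_draw(self):
        # 5 individuals, 10 distinct alleles, g = N = 10 -> A_R = 10
        rows = [[(100 + 2 * k, 102 + 2 * k)] for k in range(0, 10, 2)]
        gm = build_gm(rows)
        assert stats.rarefied_allelic_richness(gm, g=10).iloc[0].A_R == pytest.approx(10.0)

    def test_matches_resampling_oracle(self):
        rng = np.random.default_rng(42)
        copies = rng.choice([100, 102, 104, 106], size=24, p=[0.5, 0.25, 0.15, 0.1])
        rows = [[tuple(sorted(copies[2 * i:2 * i + 2]))] for i in range(12)]
        gm = build_gm(rows)
        g = 10
        ar = stats.rarefied_allelic_richness(gm, g=g).iloc[0].A_R
        # Monte-Carlo subsampling oracle
        draws = np.array(
            [len(np.unique(rng.choice(copies, size=g, replace=False))) for _ in range(20000)]
        )
        assert ar == pytest.approx(draws.mean(), abs=3 * draws.std() / math.sqrt(len(draws)))

    def test_monotone_in_g_and_full_sample_identity(self, small_world):
        gm, _ = small_world
        ft = stats.allele_frequencies(gm)
        gmax = int(ft.gene_counts.min())
        prev = None
        for g in range(2, gmax + 1, 4):
            ar = stats.rarefied_allelic_richness(gm, g=g, freqs=ft)
            if prev is not None:
                assert (ar.A_R.values >= prev - 1e-9).all()
            prev = ar.A_R.values
        full = stats.rarefied_allelic_richness(gm, g=gmax, freqs=ft)
        div = stats.diversity_table(gm, ft)
        at_min = div[div.gene_count == gmax]
        merged = at_min.merge(full, on=["population", "locus"])
        assert np.allclose(merged.A_R, merged.N_A)

    def test_error_lists_offending_cells(self):
        gm = build_gm([[(100, 104)]] * 3)  # 6 gene copies < 10
        with pytest.raises(ValidationError, match="g=10"):
            stats.rarefied_allelic_richness(gm, g=10)


class TestWcFstats:
    def test_fixed_difference_fst_one(self):
        gm = build_gm(
            [[(100, 100)]] * 8 + [[(104, 104)]] * 8,
            populations=["A"] * 8 + ["B"] * 8,
        )
        f = stats.wc_fstats(gm)
        assert f.fst == pytest.approx(1.0)

    def test_panmictic_split_near_zero(self):
        gm, _ = make_island_world(1, 60, target_fst=0.0, seed=9)
        gm.populations = np.array(
            ["A"] * 30 + ["B"] * 30, dtype=object
        )
        gm.metadata = {p: gm.metadata[list(gm.metadata)[0]] for p in ("A", "B")}
        f = stats.wc_fstats(gm, n_perm=200, seed=3)
        assert abs(f.fst) < 0.02
        assert f.p_fst > 0.05

    def test_single_group_error(self):
        gm = build_gm([[(100, 104)]] * 4)
        with pytest.raises(ValidationError):
            stats.wc_fstats(gm)

    def test_fit_identity(self, island_world):
        gm, _ = island_world
        f = stats.wc_fstats(gm)
        assert f.fit == pytest.approx(f.fst + (1 - f.fst) * f.fis, abs=1e-9)

    def test_island_model_recovery(self):
        fsts = []
        for seed in range(6):
            gm, _ = make_island_world(8, 30, target_fst=0.15, seed=seed)
            fsts.append(stats.wc_fstats(gm).fst)
        assert np.mean(fsts) == pytest.approx(0.15, abs=0.03)

    def test_oracle_small_instance(self):
        # independent per-allele variance-component computation, r = 2
        gm = build_gm(
            [[(100, 100)], [(100, 104)], [(104, 104)], [(104, 104)], [(100, 104)]],
            populations=["A", "A", "B", "B", "B"],
        )
        f = stats.wc_fstats(gm)
        na, nb = 2.0, 3.0
        nbar = 2.5
        nc = (2 * nbar - (na**2 + nb**2) / (2 * nbar)) / 1
        num = den = 0.0
        # pop A: {100/100, 100/104}; pop B: {104/104, 104/104, 100/104}
        for pa, pb, ha, hb in [(0.75, 1 / 6, 0.5, 1 / 3), (0.25, 5 / 6, 0.5, 1 / 3)]:
            pbar = (na * pa + nb * pb) / (2 * nbar)
            s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / nbar
            hbar = (na * ha + nb * hb) / (2 * nbar)
            term = pbar * (1 - pbar) - s2 / 2
            a = nbar / nc * (s2 - (term - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (term - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
        assert f.fst == pytest.approx(num / den, abs=1e-12)


def _hwe_exact_p_two_alleles(n_hom_major, n_het, n_hom_minor):
    """Exact p for the 2-allele case by enumerating heterozygote counts
    (Levene's conditional distribution)."""
    n = n_hom_major + n_het + n_hom_minor
    n_a = 2 * n_hom_major + n_het
    n_b = 2 * n_hom_minor + n_het
    def log_prob(h):
        if (n_a - h) % 2 or (n_b - h) % 2 or h > min(n_a, n_b):
            return -np.inf
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(h + 1) - gammaln(nbb + 1)
            + h * math.log(2) + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
        )
    hs = [h for h in range(min(n_a, n_b) + 1) if np.isfinite(log_prob(h))]
    probs = np.exp([log_prob(h) for h in hs])
    probs /= probs.sum()
    obs = probs[hs.index(n_het)]
    return probs[probs <= obs + 1e-12].sum()


class TestHwe:
    def test_perfect_hwe_large_p(self):
        gm = build_gm(
            [[(100, 100)]] * 25 + [[(100, 104)]] * 50 + [[(104, 104)]] * 25
        )
        r = stats.hwe_exact_test(gm, "pop1", "L1", n_perm=2000, seed=1)
        assert r.p_value > 0.5

    def test_monomorphic_p_one(self):
        gm = build_gm([[(100, 100)]] * 10)
        assert stats.hwe_exact_test(gm, "pop1", "L1", n_perm=100, seed=1).p_value == 1.0

    def test_all_heterozygotes_matches_enumeration_oracle(self):
        n = 20
        gm = build_gm([[(100, 104)]] * n)
        exact = _hwe_exact_p_two_alleles(0, n, 0)
        r = stats.hwe_exact_test(gm, "pop1", "L1", n_perm=20000, seed=2)
        assert r.p_value == pytest.approx(exact, abs=0.01)
        assert r.p_value < 0.05

    def test_reproducible_under_seed(self, island_world):
        gm, _ = island_world
        r1 = stats.hwe_exact_test(gm, "deme_1", "loc01", n_perm=500, seed=11)
        r2 = stats.hwe_exact_test(gm, "deme_1", "loc01", n_perm=500, seed=11)
        assert r1.p_value == r2.p_value

    def test_null_pvalues_uniform(self):
        # HWE-simulated data: p-values approximately Uniform(0,1)
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            copies = rng.choice([100, 104, 108], size=40, p=[0.5, 0.3, 0.2])
            rows = [[tuple(sorted(copies[2 * i:2 * i + 2]))] for i in range(20)]
            gm = build_gm(rows)
            pvals.append(
                stats.hwe_exact_test(gm, "pop1", "L1", n_perm=500,
                                     seed=int(rng.integers(2**31))).p_value
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestNullAlleles:
    def test_brookfield_formulas(self):
        assert stats.brookfield1(0.6, 0.6) == pytest.approx(0.0)
        assert stats.brookfield1(0.6, 0.4) == pytest.approx(0.125)
        assert stats.brookfield2(0.6, 0.4, 0.0) == pytest.approx(0.125)
        # with recorded blanks the estimate rises
        assert stats.brookfield2(0.6, 0.4, 0.1) > 0.125

    def test_estimate_on_cell(self, island_world):
        gm, _ = island_world
        e = stats.null_allele_estimate(gm, "deme_1", "loc01", n_boot=200, seed=5)
        assert -1 <= e.r1_raw <= 1
        assert e.r1 == max(0.0, e.r1_raw)
        assert e.r2_raw == pytest.approx(e.r1_raw)  # no blanks in this world
        assert e.ci_low is not None and e.ci_low <= e.r2_raw <= e.ci_high

    @given(he=st.floats(0.01, 0.95), ho=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_estimator1_bounds(self, he, ho):
        r = stats.brookfield1(he, ho)
        assert -1.0 <= r <= 1.0
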