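import numpy as np
import pytest
from scipy.stats import ks_2samp

from msatpop.coalescent import (
    DemographicEvent,
    Genealogy,
    MutationModel,
    ParamDraw,
    Scenario,
    Uniform,
    mutate_gsm,
    sample_priors,
    simulate_dataset,
    simulate_genealogy,
)
from msatpop.synth import default_loci
from msatpop.types import ValidationError, spawn_rng


def one_pop(n_diploid=5, N=1000):
    return Scenario("one", {"p": N}, {"p": n_diploid})


class TestPriors:
    def test_degenerate_prior_is_constant(self):
        sc = Scenario("s", {"p": Uniform(500, 500)}, {"p": 2})
        for seed in range(5):
            d = sample_priors(sc, MutationModel(), 3, seed=seed)
            assert d.values["N_p"] == 500.0

    def test_uniform_mu_mean(self):
        rng = spawn_rng(1, "t")
        sc = one_pop()
        draws = [
            sample_priors(sc, MutationModel(), 1, rng=rng).values["mu_mean"]
            for _ in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx((1e-5 + 1e-3) / 2, rel=0.03)

    def test_p_support(self):
        rng = spawn_rng(2, "t")
        sc = one_pop()
        for _ in range(2000):
            p = sample_priors(sc, MutationModel(), 1, rng=rng).values["P"]
            assert 0.1 <= p <= 0.99

    def test_per_locus_rates_gamma_around_mean(self):
        rng = spawn_rng(3, "t")
        mm = MutationModel(mu_mean=Uniform(2e-4, 2e-4))
        d = sample_priors(one_pop(), mm, 5000, rng=rng)
        assert d.locus_rates.mean() == pytest.approx(2e-4, rel=0.05)
        assert (d.locus_rates > 0).all()

    def test_shared_rate_switch(self):
        mm = MutationModel(mu_mean=Uniform(1e-4, 1e-4), shared_rate=True)
        d = sample_priors(one_pop(), mm, 4, seed=1)
        assert np.allclose(d.locus_rates, 1e-4)

    def test_admixture_rate_validated(self):
        sc = Scenario(
            "adm", {"a": 100, "b": 100, "c": 100}, {"c": 2},
            [DemographicEvent(time=10, kind="admix", pop="c",
                              source_a="a", source_b="b", rate=1.5)],
        )
        with pytest.raises(ValidationError):
            sample_priors(sc, MutationModel(), 1, seed=0)

    def test_unknown_population_reference(self):
        sc = Scenario(
            "bad", {"a": 100}, {"a": 2},
            [DemographicEvent(time=10, kind="merge", source="zz", sink="a")],
        )
        with pytest.raises(ValidationError):
            sc.validate()


class TestGenealogy:
    def test_tmrca_expectation(self):
        # 2 gene copies in a population of diploid size N: E[TMRCA] = 2N
        N = 400
        sc = Scenario("one", {"p": N}, {"p": 1})
        rng = spawn_rng(11, "tmrca")
        d = sample_priors(sc, MutationModel(), 1, rng=rng)
        t = np.array([simulate_genealogy(sc, d, rng=rng).tmrca for _ in range(4000)])
        assert t.mean() == pytest.approx(2 * N, rel=0.1)

    def test_single_diploid_two_leaves(self):
        sc = Scenario("one", {"p": 100}, {"p": 1})
        d = sample_priors(sc, MutationModel(), 1, seed=0)
        g = simulate_genealogy(sc, d, seed=1)
        assert g.n_leaves == 2
        assert (g.parent[:2] == 2).all() and g.parent[2] == -1

    def test_merge_at_zero_equals_single_pop(self):
        rng = spawn_rng(12, "merge0")
        N = 300
        sc2 = Scenario(
            "two", {"a": N, "b": N}, {"a": 2, "b": 2},
            [DemographicEvent(time=0.0, kind="merge", source="b", sink="a")],
        )
        sc1 = Scenario("one", {"a": N}, {"a": 4})
        d2 = sample_priors(sc2, MutationModel(), 1, rng=rng)
        d1 = sample_priors(sc1, MutationModel(), 1, rng=rng)
        t2 = [simulate_genealogy(sc2, d2, rng=rng).tmrca for _ in range(800)]
        t1 = [simulate_genealogy(sc1, d1, rng=rng).tmrca for _ in range(800)]
        assert ks_2samp(t1, t2).pvalue > 0.01

    def test_stranded_lineages_error(self):
        sc = Scenario("bad", {"a": 100, "b": 100}, {"a": 1, "b": 1})
        d = sample_priors(sc, MutationModel(), 1, seed=0)
        with pytest.raises(ValidationError, match="stranded"):
            simulate_genealogy(sc, d, seed=1)

    def test_size_change_event(self):
        # crash-test only: huge ancestral size slows coalescence but completes
        sc = Scenario(
            "sc", {"a": 50}, {"a": 3},
            [DemographicEvent(time=10.0, kind="size_change", pop="a", size=5000)],
        )
        d = sample_priors(sc, MutationModel(), 1, seed=3)
        g = simulate_genealogy(sc, d, seed=4)
        assert g.tmrca > 10.0

    def test_admixture_event_runs(self):
        sc = Scenario(
            "adm", {"a": 200, "b": 200, "c": 200}, {"c": 4},
            [
                DemographicEvent(time=50, kind="admix", pop="c",
                                 source_a="a", source_b="b", rate=0.5),
                DemographicEvent(time=5000, kind="merge", source="b", sink="a"),
            ],
        )
        d = sample_priors(sc, MutationModel(), 1, seed=5)
        g = simulate_genealogy(sc, d, seed=6)
        assert g.n_leaves == 8 and np.isfinite(g.tmrca)


def star_genealogy(n, T):
    parent = np.full(n + 1, n, dtype=np.int64)
    parent[n] = -1
    times = np.zeros(n + 1)
    times[n] = T
    return Genealogy(parent, times, n, ["p"] * n)


class TestMutation:
    def test_zero_rate_all_root_allele(self):
        g = star_genealogy(50, 1000.0)
        alleles = mutate_gsm(g, rate=0.0, p_geom=0.5, mu_sni=0.0,
                             motif_length=2, n_states=40, seed=1)
        assert np.unique(alleles).size == 1

    def test_geometric_step_mean_two_at_half(self):
        # branches with ~exactly one mutation: |step| is geometric(1-P),
        # mean 1/(1-P) = 2 at P = 0.5
        g = star_genealogy(150_000, 1.0)
        alleles = mutate_gsm(g, rate=0.05, p_geom=0.5, mu_sni=0.0,
                             motif_length=1, n_states=4001, seed=2)
        root = 2000  # n_states // 2
        moved = np.abs(alleles - root)
        steps = moved[moved > 0]
        assert steps.mean() == pytest.approx(2.0, abs=0.1)

    def test_congruent_modulo_motif_without_sni(self):
        sc = one_pop(10, 800)
        mm = MutationModel(mu_sni=Uniform(0.0, 0.0))
        gm, _ = simulate_dataset(sc, mm, default_loci(), seed=7)
        for j, locus in enumerate(gm.loci):
            obs = gm.calls[:, j, :].ravel()
            assert np.unique(obs % locus.motif_length).size == 1

    def test_sni_breaks_lattice(self):
        g = star_genealogy(3000, 2000.0)
        alleles = mutate_gsm(g, rate=0.0, p_geom=0.5, mu_sni=5e-4,
                             motif_length=3, n_states=40, seed=3)
        assert np.unique(alleles % 3).size > 1
        # offsets capped at +-2 around the root state
        assert alleles.min() >= 20 * 3 - 2 and alleles.max() <= 20 * 3 + 2

    def test_reflection_keeps_states_in_range(self):
        g = star_genealogy(2000, 5000.0)
        alleles = mutate_gsm(g, rate=0.01, p_geom=0.8, mu_sni=0.0,
                             motif_length=2, n_states=10, seed=4)
        assert alleles.min() >= 0 and alleles.max() <= 9 * 2

    def test_smm_closed_form_homozygosity(self):
        # strict SMM (P -> 0), theta = 4*N*mu = 1: E[hom] = 1/sqrt(1+2*theta)
        N, mu = 2500, 1e-4
        sc = Scenario("smm", {"p": N}, {"p": 10})
        rng = spawn_rng(5, "smm")
        d = ParamDraw("smm", {"N_p": N, "P": 1e-12, "mu_sni": 0.0, "mu_mean": mu},
                      np.array([mu]), None)
        hom = []
        for _ in range(3000):
            g = simulate_genealogy(sc, d, rng=rng)
            al = mutate_gsm(g, mu, 1e-12, 0.0, 2, n_states=2000, rng=rng)
            p = np.bincount(al) / len(al)
            n = len(al)
            hom.append((np.sum(p**2) * n - 1) / (n - 1))  # unbiased estimator
        expect = 1 / np.sqrt(3)
        se = np.std(hom) / np.sqrt(len(hom))
        assert np.mean(hom) == pytest.approx(expect, abs=max(4 * se, 0.01))


class TestSimulateDataset:
    def test_deterministic_under_seed(self):
        sc = one_pop(6, 500)
        mm = MutationModel()
        g1, d1 = simulate_dataset(sc, mm, default_loci(), seed=9)
        g2, d2 = simulate_dataset(sc, mm, default_loci(), seed=9)
        assert np.array_equal(g1.calls, g2.calls)
        assert d1.values == d2.values

    def test_sizes_within_declared_ranges(self):
        sc = one_pop(8, 1000)
        gm, _ = simulate_dataset(sc, MutationModel(), default_loci(), seed=10)
        for j, locus in enumerate(gm.loci):
            obs = gm.calls[:, j, :]
            assert obs.min() >= locus.size_range[0]
            assert obs.max() <= locus.size_range[1]

    def test_heterozygosity_increases_with_n(self):
        from msatpop import stats as mstats

        mm = MutationModel(mu_mean=Uniform(2e-4, 2e-4), p_geom=Uniform(0.3, 0.3),
                           mu_sni=Uniform(0.0, 0.0))
        hets = []
        for N in (200, 5000):
            sc = Scenario("n", {"p": N}, {"p": 15})
            vals = []
            for seed in range(25):
                gm, _ = simulate_dataset(sc, mm, default_loci(), seed=seed)
                div = mstats.diversity_table(gm)
                vals.append(div.H_E.mean())
            hets.append(np.mean(vals))
        assert hets[1] > hets[0]
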