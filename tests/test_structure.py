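import math

import numpy as np
import pytest

from msatpop import stats, structure
from msatpop.structure import DistanceMatrix
from msatpop.synth import make_island_world
from msatpop.types import ValidationError
from .conftest import build_gm


class TestPairwiseFst:
    def test_identical_populations_near_zero(self):
        gm, _ = make_island_world(1, 40, target_fst=0.0, seed=21)
        gm.populations = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        gm.metadata = {p: list(gm.metadata.values())[0] for p in ("A", "B")}
        dm, _ = structure.pairwise_fst_matrix(gm)
        assert abs(dm.values[0, 1]) < 0.03  # raw value may be < 0
        assert dm.truncated().values[0, 1] >= 0.0

    def test_matches_wc_fstats_on_each_pair(self, small_world):
        gm, _ = small_world
        dm, _ = structure.pairwise_fst_matrix(gm)
        idx = gm.population_indices()
        pops = gm.population_ids
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                rows = np.concatenate([idx[pops[i]], idx[pops[j]]])
                f = stats.wc_fstats(gm.subset(rows))
                assert dm.values[i, j] == pytest.approx(f.fst, abs=1e-12)

    def test_pair_count(self, island_world):
        gm, _ = island_world
        dm, _ = structure.pairwise_fst_matrix(gm)
        n = len(dm.labels)
        assert dm.condensed().size == n * (n - 1) // 2

    def test_permutation_pvalues(self, small_world):
        gm, _ = small_world
        dm, pmat = structure.pairwise_fst_matrix(gm, n_perm=50, seed=1)
        off = pmat.values[np.triu_indices(len(dm.labels), k=1)]
        assert ((off > 0) & (off <= 1)).all()

    def test_single_population_error(self):
        gm = build_gm([[(100, 104)]] * 4)
        with pytest.raises(ValidationError):
            structure.pairwise_fst_matrix(gm)


class TestChordDistance:
    def test_identical_frequencies_zero(self):
        gm = build_gm(
            [[(100, 104)], [(100, 104)]], populations=["A", "B"]
        )
        ft = stats.allele_frequencies(gm)
        dm = structure.chord_distance_matrix(ft)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_single_locus(self):
        gm = build_gm(
            [[(100, 100)], [(104, 104)]], populations=["A", "B"]
        )
        dm = structure.chord_distance_matrix(stats.allele_frequencies(gm))
        assert dm.values[0, 1] == pytest.approx(2 / math.pi * math.sqrt(2), abs=1e-9)
        assert dm.values[0, 1] == pytest.approx(0.9003, abs=1e-4)

    def test_no_shared_locus_error(self):
        gm = build_gm(
            [[(100, 100), None], [None, (150, 150)]], populations=["A", "B"]
        )
        with pytest.raises(ValidationError):
            structure.chord_distance_matrix(stats.allele_frequencies(gm))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=5, d(B,C)=6 -> branch lengths (1, 2, 4)
        D = np.array([[0, 3, 5], [0, 0, 6], [0, 0, 0]], dtype=float)
        D = D + D.T
        tree = structure.neighbor_joining(DistanceMatrix(list("ABC"), D))
        assert tree.path_distance("A", "B") == pytest.approx(3)
        assert tree.path_distance("A", "C") == pytest.approx(5)
        assert tree.path_distance("B", "C") == pytest.approx(6)

    def test_additive_five_taxon_recovery(self):
        paths = {
            ("A", "B"): 5, ("A", "C"): 6, ("A", "D"): 9, ("A", "E"): 8,
            ("B", "C"): 7, ("B", "D"): 10, ("B", "E"): 9,
            ("C", "D"): 5, ("C", "E"): 8, ("D", "E"): 11,
        }
        labels = list("ABCDE")
        D = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = labels.index(x), labels.index(y)
            D[i, j] = D[j, i] = v
        tree = structure.neighbor_joining(DistanceMatrix(labels, D))
        for (x, y), v in paths.items():
            assert tree.path_distance(x, y) == pytest.approx(v, abs=1e-9)
        assert tree.newick.endswith(";")

    def test_star_topology_zero_internal(self):
        # ultrametric star: all pairwise distances equal
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = structure.neighbor_joining(DistanceMatrix(list("ABCD"), D))
        for a, b in [("A", "B"), ("A", "C"), ("C", "D")]:
            assert tree.path_distance(a, b) == pytest.approx(2.0, abs=1e-9)

    def test_rejects_asymmetric(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            structure.neighbor_joining(DistanceMatrix(list("ABC"), D))

    def test_needs_three_labels(self):
        D = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            structure.neighbor_joining(DistanceMatrix(list("AB"), D))


class TestAmova:
    def test_percentages_sum_100(self, island_world):
        gm, _ = island_world
        res = structure.amova(gm, ["population"], n_perm=0)
        assert res.percentages.sum() == pytest.approx(100.0, abs=0.01)

    def test_panmictic_within_individuals_dominates(self):
        gm, _ = make_island_world(4, 20, target_fst=0.0, seed=31)
        res = structure.amova(gm, ["population"], n_perm=0)
        assert abs(res.percentages[0]) < 3.0
        assert res.percentages[-1] > 90.0

    def test_island_model_matches_theory(self):
        pcts = []
        for seed in range(5):
            gm, _ = make_island_world(8, 25, target_fst=0.2, seed=40 + seed)
            res = structure.amova(gm, ["population"], n_perm=0)
            pcts.append(res.percentages[0])
        assert np.mean(pcts) == pytest.approx(20.0, abs=3.0)

    def test_four_level_hierarchy(self, island_world):
        gm, _ = island_world
        # invent a two-group split of the demes via subcontinent metadata
        from msatpop.types import PopulationMetadata

        for i, p in enumerate(gm.population_ids):
            gm.metadata[p] = PopulationMetadata(
                p, subcontinent="Africa" if i < 2 else "Europe"
            )
        res = structure.amova(gm, ["subcontinent", "population"], n_perm=20, seed=2)
        assert len(res.levels) == 4
        assert res.percentages.sum() == pytest.approx(100.0, abs=0.01)
        assert "phi_CT" in res.phi and "phi_SC" in res.phi
        assert set(res.p_values) == set(res.levels[:-1])

    def test_structured_data_significant(self, island_world):
        gm, _ = island_world
        res = structure.amova(gm, ["population"], n_perm=49, seed=5)
        assert res.p_values[res.levels[0]] <= 0.05

    def test_unknown_factor(self, island_world):
        gm, _ = island_world
        with pytest.raises(ValidationError):
            structure.amova(gm, ["planet"], n_perm=0)


class TestMantel:
    def _random_sym(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_perfect_correlation(self):
        rng = np.random.default_rng(3)
        x = self._random_sym(rng, 6)
        res = structure.mantel(x, x.copy(), n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_exact_enumeration_on_four(self):
        rng = np.random.default_rng(8)
        x = self._random_sym(rng, 4)
        y = self._random_sym(rng, 4)
        exact = structure.mantel(x, y, exact=True)
        assert exact.n_perm == 24
        # oracle: direct enumeration independent of the implementation
        import itertools

        iu = np.triu_indices(4, k=1)

        def corr(a, b):
            av, bv = a[iu], b[iu]
            av = av - av.mean()
            bv = bv - bv.mean()
            return float(av @ bv / np.sqrt((av @ av) * (bv @ bv)))

        obs = corr(x, y)
        count = sum(
            corr(x, y[np.ix_(p, p)]) >= obs - 1e-12
            for p in itertools.permutations(range(4))
        )
        assert exact.p_value == pytest.approx(count / 24)

    def test_invariant_under_joint_relabelling(self):
        rng = np.random.default_rng(9)
        x = self._random_sym(rng, 7)
        y = self._random_sym(rng, 7)
        p = rng.permutation(7)
        r1 = structure.mantel(x, y, n_perm=10, seed=0).r
        r2 = structure.mantel(x[np.ix_(p, p)], y[np.ix_(p, p)], n_perm=10, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_needs_four(self):
        with pytest.raises(ValidationError):
            structure.mantel(np.zeros((3, 3)), np.zeros((3, 3)))

    def test_ibd_wrapper(self, small_world):
        gm, _ = small_world
        dm, _ = structure.pairwise_fst_matrix(gm)
        coords = {"deme_1": (0.0, 0.0), "deme_2": (10.0, 10.0), "deme_3": (-20.0, 30.0)}
        with pytest.raises(ValidationError):
            structure.mantel_ibd(dm, coords)  # only 3 populations
        gm4, _ = make_island_world(4, 12, target_fst=0.1, seed=77)
        dm4, _ = structure.pairwise_fst_matrix(gm4)
        coords4 = {p: (float(i * 5), float(i * 3)) for i, p in enumerate(dm4.labels)}
        res = structure.mantel_ibd(dm4, coords4, n_perm=99, seed=1)
        assert -1 <= res.r <= 1

    def test_ibd_coincident_coordinates_floor(self):
        gm4, _ = make_island_world(4, 12, target_fst=0.1, seed=78)
        dm4, _ = structure.pairwise_fst_matrix(gm4)
        coords = {p: (1.0, 1.0) for p in dm4.labels}  # all coincident
        res = structure.mantel_ibd(dm4, coords, n_perm=19, seed=1)
        assert np.isnan(res.r)  # zero geographic variance -> undefined r

    def test_haversine(self):
        # quarter of the equator
        assert structure.haversine_km(0, 0, 0, 90) == pytest.approx(10_007.5, rel=1e-3)


class TestEmCluster:
    def test_fixed_difference_memberships(self):
        gm = build_gm(
            [[(100, 100)]] * 10 + [[(104, 104)]] * 10,
            populations=["A"] * 10 + ["B"] * 10,
        )
        m = structure.em_cluster(gm, 2, n_restarts=3, seed=1)
        post = m.posteriors
        groups = post.argmax(axis=1)
        assert (groups[:10] == groups[0]).all() and (groups[10:] == groups[10]).all()
        assert groups[0] != groups[10]
        assert np.allclose(post.max(axis=1), 1.0, atol=1e-6)
        # logL equals the sum of per-genotype log frequencies (p^2 = 1)
        assert m.log_likelihood == pytest.approx(20 * math.log(0.5), abs=1e-6)

    def test_posteriors_row_sum_one(self, small_world):
        gm, _ = small_world
        m = structure.em_cluster(gm, 3, n_restarts=2, seed=2)
        assert np.allclose(m.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_monotone(self, small_world):
        gm, _ = small_world
        m = structure.em_cluster(gm, 2, n_restarts=2, seed=3)
        assert np.all(np.diff(m.loglik_trace) >= -1e-6)

    def test_three_deme_assignment(self):
        gm, truth = make_island_world(3, 40, target_fst=0.15, seed=55)
        m = structure.em_cluster(gm, 3, n_restarts=4, seed=4)
        true = np.array([truth.params["true_deme"][i] for i in gm.individuals])
        from sklearn.metrics import adjusted_rand_score

        # >= 95% correct assignment corresponds to near-perfect ARI
        best = 0.0
        labels = m.assignments
        match = 0
        for d in np.unique(true):
            vals, counts = np.unique(labels[true == d], return_counts=True)
            match += counts.max()
        assert match / len(true) >= 0.95
        assert adjusted_rand_score(true, labels) > 0.85

    def test_k_bounds(self, small_world):
        gm, _ = small_world
        with pytest.raises(ValidationError):
            structure.em_cluster(gm, 0)
        with pytest.raises(ValidationError):
            structure.em_cluster(gm, gm.n_individuals + 1)


class TestSelectK:
    def test_panmictic_selects_one(self):
        gm, _ = make_island_world(1, 60, target_fst=0.0, seed=66)
        best, table, _ = structure.select_k(gm, range(1, 5), seed=5, n_restarts=3)
        assert best == 1

    def test_four_cluster_recovery(self):
        hits = 0
        for seed in range(10):
            gm, _ = make_island_world(4, 25, target_fst=0.18, seed=600 + seed)
            best, _, _ = structure.select_k(gm, range(1, 8), seed=seed, n_restarts=3)
            hits += best == 4
        assert hits >= 9

    def test_kic_penalty_increases_with_k(self, small_world):
        gm, _ = small_world
        _, table, models = structure.select_k(gm, range(1, 5), seed=6, n_restarts=2)
        nus = table.sort_values("K").nu.values
        assert (np.diff(nus) > 0).all()
        # at fixed logL the criterion strictly increases with nu
        kics = -2 * table.logL.values[0] + 3 * (table.sort_values("K").nu.values + 1)
        assert (np.diff(kics) > 0).all()

    def test_unknown_criterion(self, small_world):
        gm, _ = small_world
        with pytest.raises(ValidationError):
            structure.select_k(gm, [2], criterion="DIC")


class TestHybridClassify:
    def test_query_identical_to_parent_profile(self):
        rng = np.random.default_rng(12)
        rows_a = [[(100, 100), (150, 150)] for _ in range(8)]
        rows_b = [[(104, 104), (152, 152)] for _ in range(8)]
        gm = build_gm(rows_a + rows_b + [rows_a[0]],
                      populations=["A"] * 8 + ["B"] * 8 + ["Q"])
        res = structure.hybrid_classify(gm, np.arange(8), np.arange(8, 16), [16])
        assert res.posteriors.iloc[0]["pure_A"] > 0.99

    def test_parental_sets_must_be_disjoint(self, small_world):
        gm, _ = small_world
        with pytest.raises(ValidationError):
            structure.hybrid_classify(gm, np.arange(6), np.arange(5, 11), [20])

    def test_parental_sets_min_size(self, small_world):
        gm, _ = small_world
        with pytest.raises(ValidationError):
            structure.hybrid_classify(gm, np.arange(3), np.arange(5, 11), [20])

    def test_posteriors_sum_one(self):
        from msatpop.synth import make_hybrid_panel

        gm, _ = make_hybrid_panel(0.3, n_pure=10, n_f1=5, n_bc=5, seed=9)
        idx = gm.population_indices()
        res = structure.hybrid_classify(gm, idx["pure_A"], idx["pure_B"], idx["F1"])
        assert np.allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)


class TestDapc:
    def test_fixed_difference_perfect_assignment(self):
        gm = build_gm(
            [[(100, 100), (150, 150)]] * 12 + [[(104, 104), (152, 152)]] * 12,
            populations=["A"] * 12 + ["B"] * 12,
        )
        res = structure.dapc(gm, n_pc=2, seed=1)
        assert (res.group_assignment.values == np.array(["A"] * 12 + ["B"] * 12)).all()
        assert res.coordinates.shape[1] == 1  # one discriminant axis for 2 groups

    def test_cv_selects_reasonable_npc(self):
        gm, _ = make_island_world(3, 25, target_fst=0.2, seed=88)
        res = structure.dapc(gm, seed=2)
        cv = res.cross_validation
        assert cv is not None
        best = cv.success.max()
        chosen = cv[cv.n_pc == res.n_pc].success.iloc[0]
        assert chosen >= best - 0.02

    def test_npc_too_large(self, small_world):
        gm, _ = small_world
        with pytest.raises(ValidationError):
            structure.dapc(gm, n_pc=gm.n_individuals, seed=1)

    def test_needs_two_groups(self):
        gm = build_gm([[(100, 104)]] * 6)
        with pytest.raises(ValidationError):
            structure.dapc(gm)


class TestFca:
    def test_mirror_symmetry_on_axis1(self):
        # two groups with mirrored frequency profiles -> barycentres
        # symmetric about the origin on axis 1 (third group at centre)
        rows_a = [[(100, 100)]] * 8 + [[(104, 104)]] * 2
        rows_b = [[(100, 100)]] * 2 + [[(104, 104)]] * 8
        rows_c = [[(100, 100)]] * 5 + [[(104, 104)]] * 5
        gm = build_gm(rows_a + rows_b + rows_c,
                      populations=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        res = structure.fca(gm)
        b = res.barycentres["CA1"]
        assert b["A"] == pytest.approx(-b["B"], abs=1e-9)
        assert b["C"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_ca_oracle(self):
        gm, _ = make_island_world(3, 10, target_fst=0.2, seed=99)
        res = structure.fca(gm)
        # independent CA: eigen-decomposition route on the same dosage table
        from msatpop.structure import _dosage_blocks

        _, _, X = _dosage_blocks(gm)
        X = X[:, X.sum(axis=0) > 0]
        X = X[:, ~np.all(X == X[0, :], axis=0)]
        P = X / X.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        E = np.outer(r, c)
        chi = (P - E) / np.sqrt(E)
        vals = np.linalg.eigvalsh(chi @ chi.T)[::-1]
        vals = vals[vals > 1e-12]
        assert np.allclose(
            np.sort(res.eigenvalues)[::-1][: len(vals)], vals, atol=1e-8
        )

    def test_explained_fractions(self, small_world):
        gm, _ = small_world
        res = structure.fca(gm)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_needs_three_populations(self):
        gm = build_gm([[(100, 104)]] * 6, populations=["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValidationError):
            structure.fca(gm)


class TestDistanceMatrixExport:
    def test_phylip_text(self):
        dm = DistanceMatrix(["alpha", "beta"], np.array([[0.0, 0.5], [0.5, 0.0]]))
        text = dm.to_phylip()
        lines = text.strip().splitlines()
        assert lines[0].strip() == "2"
        assert lines[1].startswith("alpha") and "0.500000" in lines[1]
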