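"""Population structure: pairwise differentiation, distance matrices and
trees, hierarchical AMOVA, isolation by distance, maximum-likelihood mixture
clustering with information-criterion selection, hybrid-class assignment and
multivariate ordinations."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import FreqTable, allele_frequencies, wc_fstats
from .types import GenotypeMatrix, ValidationError, spawn_rng

__all__ = [
    "DistanceMatrix",
    "Tree",
    "AmovaResult",
    "MantelResult",
    "ClusterModel",
    "HybridClassResult",
    "OrdinationResult",
    "pairwise_fst_matrix",
    "chord_distance_matrix",
    "neighbor_joining",
    "amova",
    "mantel",
    "mantel_ibd",
    "haversine_km",
    "em_cluster",
    "select_k",
    "hybrid_classify",
    "dapc",
    "fca",
]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "fst"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix is not symmetric")
        self.values = v

    def truncated(self) -> "DistanceMatrix":
        """Non-negative view (pairwise FST may be negative pre-truncation)."""
        return DistanceMatrix(self.labels, np.maximum(self.values, 0.0), self.kind)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """Square PHYLIP distance-matrix text."""
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            name = f"{lab[:10]:<10}"
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _pairwise_theta_components(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accumulated Weir–Cockerham numerator (a) and denominator (a+b+c)
    sums over loci for every unordered population pair, vectorised."""
    pops = gm.population_ids
    P = len(pops)
    idx = gm.population_indices()
    iu, ju = np.triu_indices(P, k=1)
    num = np.zeros(iu.size)
    den = np.zeros(iu.size)
    for j in range(gm.n_loci):
        codes, sizes = gm.locus_codes(j)
        A = sizes.size
        if A == 0:
            continue
        n = np.zeros(P)
        pfreq = np.zeros((P, A))
        hfreq = np.zeros((P, A))
        for g, pid in enumerate(pops):
            sub = codes[idx[pid]]
            ok = sub[:, 0] >= 0
            m = int(ok.sum())
            n[g] = m
            if m == 0:
                continue
            typed = sub[ok]
            cnt = np.bincount(typed.ravel(), minlength=A)
            pfreq[g] = cnt / (2.0 * m)
            het = typed[:, 0] != typed[:, 1]
            if het.any():
                hcnt = np.bincount(typed[het].ravel(), minlength=A)
                hfreq[g] = hcnt / m  # each het individual carries the allele once
        ni, nj = n[iu], n[ju]
        usable = (ni >= 1) & (nj >= 1) & (ni + nj > 2)
        if not usable.any():
            continue
        ni, nj = ni[usable], nj[usable]
        pi, pj = pfreq[iu[usable]], pfreq[ju[usable]]
        hi, hj = hfreq[iu[usable]], hfreq[ju[usable]]
        nbar = (ni + nj) / 2.0
        nc = 2.0 * nbar - (ni**2 + nj**2) / (2.0 * nbar)
        pbar = (ni[:, None] * pi + nj[:, None] * pj) / (2.0 * nbar[:, None])
        s2 = (ni[:, None] * (pi - pbar) ** 2 + nj[:, None] * (pj - pbar) ** 2) / nbar[:, None]
        hbar = (ni[:, None] * hi + nj[:, None] * hj) / (2.0 * nbar[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            term = pbar * (1 - pbar) - s2 / 2.0
            a = nbar[:, None] / nc[:, None] * (
                s2 - (term - hbar / 4.0) / (nbar[:, None] - 1.0)
            )
            b = nbar[:, None] / (nbar[:, None] - 1.0) * (
                term - (2 * nbar[:, None] - 1) / (4 * nbar[:, None]) * hbar
            )
        c = hbar / 2.0
        good = (nc > 0) & (nbar > 1)
        contrib_a = np.where(good[:, None], a, 0.0).sum(axis=1)
        contrib_d = np.where(good[:, None], a + b + c, 0.0).sum(axis=1)
        num[np.flatnonzero(usable)] += np.nan_to_num(contrib_a)
        den[np.flatnonzero(usable)] += np.nan_to_num(contrib_d)
    return num, den, pops


def pairwise_fst_matrix(
    gm: GenotypeMatrix, n_perm: int = 0, seed: int | None = None
) -> tuple[DistanceMatrix, pd.DataFrame | None]:
    """Weir–Cockerham theta for every unordered population pair.

    Raw (possibly negative) values are stored; use ``.truncated()`` for the
    clamped view.  With ``n_perm > 0`` a permutation p-value per pair is
    computed by shuffling individuals between the two populations.
    """
    pops = gm.population_ids
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations")
    num, den, pops = _pairwise_theta_components(gm)
    P = len(pops)
    iu, ju = np.triu_indices(P, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den != 0, num / den, np.nan)
    mat = np.zeros((P, P))
    mat[iu, ju] = theta
    mat[ju, iu] = theta
    dm = DistanceMatrix(pops, mat, kind="fst")
    pmat = None
    if n_perm > 0:
        idx = gm.population_indices()
        rng = spawn_rng(seed, "pairwise_fst")
        pvals = np.full((P, P), np.nan)
        for k in range(iu.size):
            pa, pb = pops[iu[k]], pops[ju[k]]
            rows = np.concatenate([idx[pa], idx[pb]])
            na = len(idx[pa])
            sub = gm.subset(rows)
            obs = theta[k]
            hits = 0
            labels = np.array(["a"] * na + ["b"] * (len(rows) - na), dtype=object)
            for _ in range(n_perm):
                perm = rng.permutation(len(rows))
                sub.populations = labels[perm]
                f = wc_fstats(sub)
                if f.fst >= obs - 1e-12:
                    hits += 1
            pvals[iu[k], ju[k]] = pvals[ju[k], iu[k]] = (hits + 1) / (n_perm + 1)
        pmat = pd.DataFrame(pvals, index=pops, columns=pops)
    return dm, pmat


def chord_distance_matrix(freqs: FreqTable) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distances between groups.

    D = (2 / (pi * L)) * sum_l sqrt(2 * (1 - sum_a sqrt(p_a * q_a))) over the
    L loci typed in both groups.
    """
    G = freqs.n_groups
    mat = np.zeros((G, G))
    fj = [freqs.frequencies(j) for j in range(freqs.n_loci)]
    for g1 in range(G):
        for g2 in range(g1 + 1, G):
            total = 0.0
            nloc = 0
            for j in range(freqs.n_loci):
                if freqs.gene_counts[g1, j] == 0 or freqs.gene_counts[g2, j] == 0:
                    continue
                p, q = fj[j][g1], fj[j][g2]
                cos_theta = float(np.sum(np.sqrt(np.clip(p * q, 0, None))))
                total += math.sqrt(max(0.0, 2.0 * (1.0 - cos_theta)))
                nloc += 1
            if nloc == 0:
                raise ValidationError(
                    f"no shared typed locus between {freqs.groups[g1]} and {freqs.groups[g2]}"
                )
            d = 2.0 / (math.pi * nloc) * total
            mat[g1, g2] = mat[g2, g1] = d
    return DistanceMatrix(list(freqs.groups), mat, kind="chord")


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Unrooted tree as a Newick string plus edge list for path metrics."""

    newick: str
    leaves: list[str]
    edges: list[tuple[int, int, float]]
    node_names: dict[int, str]

    def path_distance(self, a: str, b: str) -> float:
        import networkx as nx  # local import: only needed for metrics

        g = nx.Graph()
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        name_to_id = {v: k for k, v in self.node_names.items()}
        return nx.shortest_path_length(
            g, name_to_id[a], name_to_id[b], weight="weight"
        )


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining with the Studier–Keppler Q criterion.

    Negative branch lengths are clamped to zero.  On additive input the
    generating topology and branch lengths are recovered exactly.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("neighbour joining needs at least 3 labels")
    D = dist.values.astype(float).copy()
    active = list(range(n))
    node_names = {i: lab for i, lab in enumerate(dist.labels)}
    next_id = n
    children: dict[int, list[tuple[int, float]]] = {}
    Dmap = {i: {j: D[i, j] for j in range(n) if j != i} for i in range(n)}

    while len(active) > 2:
        m = len(active)
        r = {i: sum(Dmap[i][j] for j in active if j != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * Dmap[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = Dmap[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = next_id
        next_id += 1
        children[new] = [(i, li), (j, lj)]
        Dmap[new] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (Dmap[i][k] + Dmap[j][k] - dij)
            Dmap[new][k] = dk
            Dmap[k][new] = dk
        active = [k for k in active if k not in (i, j)] + [new]
    i, j = active
    children.setdefault(i, [])
    # join the final two nodes with the remaining distance on one edge
    final_len = max(0.0, Dmap[i][j])
    edges: list[tuple[int, int, float]] = []

    def collect(node: int) -> None:
        for child, ln in children.get(node, []):
            edges.append((node, child, ln))
            collect(child)

    collect(i)
    collect(j)
    edges.append((i, j, final_len))
    if not children.get(i):  # root the newick at an internal node
        i, j = j, i

    def newick_of(node: int, parent: int | None) -> str:
        nbrs = []
        for u, v, w in edges:
            if u == node and v != parent:
                nbrs.append((v, w))
            elif v == node and u != parent:
                nbrs.append((u, w))
        if node < n and not children.get(node):
            return node_names[node]
        parts = [f"{newick_of(c, node)}:{w:.10g}" for c, w in nbrs]
        return "(" + ",".join(parts) + ")"

    newick = newick_of(i, None) + ";"
    return Tree(newick=newick, leaves=list(dist.labels), edges=edges, node_names=node_names)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    levels: list[str]
    sigma2: np.ndarray
    percentages: np.ndarray
    phi: dict[str, float]
    ss: np.ndarray
    df: np.ndarray
    p_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "df": self.df,
                "SS": self.ss,
                "sigma2": self.sigma2,
                "percent": self.percentages,
            }
        )


def _cluster_ids(labels: list[np.ndarray]) -> np.ndarray:
    """Integer cluster id per observation for the combined label tuple."""
    combo = labels[0].astype(str)
    for lab in labels[1:]:
        combo = np.char.add(np.char.add(combo, "\x1f"), lab.astype(str))
    _, ids = np.unique(combo, return_inverse=True)
    return ids


def _ss_of_groups(values: np.ndarray, ids: np.ndarray, n_states: int) -> float:
    """Sum over clusters of (M^2 - sum_a c_a^2) / (2M) for 0/1 mismatch
    distances between gene copies, computed from allele-state counts."""
    n_clusters = ids.max() + 1
    counts = np.zeros((n_clusters, n_states), dtype=np.int64)
    np.add.at(counts, (ids, values), 1)
    M = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = (M**2 - (counts.astype(float) ** 2).sum(axis=1)) / (2.0 * M)
    return float(np.nansum(ss))


def _k_coeff(sizes_by_level: list[np.ndarray], parents: list[np.ndarray], t: int, s: int) -> float:
    """K(t, s) = sum over level-t clusters c of sum_{d in level s, d within c}
    n_d^2 / n_c.  Levels are indexed top (0) to deepest; t = -1 means the
    grand total."""
    n_s = sizes_by_level[s]
    if t == -1:
        return float(np.sum(n_s.astype(float) ** 2) / n_s.sum())
    # map each level-s cluster to its ancestor at level t
    anc = np.arange(len(n_s))
    for lvl in range(s, t, -1):
        anc = parents[lvl][anc]
    n_t = sizes_by_level[t].astype(float)
    num = np.zeros(len(n_t))
    np.add.at(num, anc, n_s.astype(float) ** 2)
    return float(np.sum(num / n_t))


def _amova_single_locus(
    values: np.ndarray, level_labels: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SS, df and variance components for one locus.

    ``values``: allele state codes per gene copy; ``level_labels``: per-copy
    label arrays from the top grouping down to the individual id.
    """
    n_states = int(values.max()) + 1
    L = len(level_labels)  # number of nested factors incl. individual
    ids_by_level = [_cluster_ids(level_labels[: t + 1]) for t in range(L)]
    sizes_by_level = [np.bincount(ids) for ids in ids_by_level]
    # parent maps: for level lvl (>=1), cluster -> parent cluster at lvl-1
    parents: list[np.ndarray] = [np.zeros(0, dtype=int)]
    for lvl in range(1, L):
        par = np.zeros(sizes_by_level[lvl].size, dtype=int)
        par[ids_by_level[lvl]] = ids_by_level[lvl - 1]
        parents.append(par)

    N = len(values)
    f_total = _ss_of_groups(values, np.zeros(N, dtype=int), n_states)
    f_levels = [_ss_of_groups(values, ids_by_level[t], n_states) for t in range(L)]
    m = [sizes_by_level[t].size for t in range(L)]

    ss = np.empty(L + 1)
    df = np.empty(L + 1)
    ss[0] = f_total - f_levels[0]
    df[0] = m[0] - 1
    for t in range(1, L):
        ss[t] = f_levels[t - 1] - f_levels[t]
        df[t] = m[t] - m[t - 1]
    ss[L] = f_levels[L - 1]  # within deepest clusters (within individuals)
    df[L] = N - m[L - 1]

    # coefficient matrix: E[SS_t] = sum_s coef[t, s] * sigma2_s
    ncomp = L + 1
    coef = np.zeros((ncomp, ncomp))
    for t in range(L):
        coef[t, L] = df[t]  # residual component
        for s in range(t, L):
            k_t = _k_coeff(sizes_by_level, parents, t, s)
            k_up = _k_coeff(sizes_by_level, parents, t - 1, s)
            coef[t, s] = k_t - k_up
    coef[L, L] = df[L]
    sigma2 = np.linalg.lstsq(coef, ss, rcond=None)[0]
    return ss, df, sigma2


def amova(
    gm: GenotypeMatrix,
    hierarchy: Sequence[str],
    n_perm: int = 99,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on allele mismatches.

    ``hierarchy`` names metadata factors from the top down, e.g.
    ``("subcontinent", "population")``; the individual and within-individual
    levels are implicit.  Components use nested-ANOVA expected mean squares
    with unequal sizes; negative components are reported, not zeroed.
    Permutation p-values: allele copies among individuals within the deepest
    factor (within-individual level), individuals among units of the deepest
    factor (among-individual level), and whole units among parents for the
    upper levels.
    """
    factor_values = {
        "population": np.asarray(gm.populations, dtype=object),
        "provenance": np.asarray(
            [gm.metadata[p].provenance for p in gm.populations], dtype=object
        ),
        "subcontinent": np.asarray(
            [gm.metadata[p].subcontinent for p in gm.populations], dtype=object
        ),
    }
    labels_ind: list[np.ndarray] = []
    for f in hierarchy:
        if f not in factor_values:
            raise ValidationError(f"unknown hierarchy factor {f!r}")
        labels_ind.append(factor_values[f])
    labels_ind.append(np.asarray(gm.individuals, dtype=object))

    def run(
        labels_per_ind: list[np.ndarray],
        shuffle_copies_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        L = len(labels_per_ind)
        tot_ss = np.zeros(L + 1)
        tot_df = np.zeros(L + 1)
        tot_sig = np.zeros(L + 1)
        pops_ind = np.asarray(gm.populations, dtype=object)
        for j in range(gm.n_loci):
            codes, _ = gm.locus_codes(j)
            ok = codes[:, 0] >= 0
            if ok.sum() < 2:
                continue
            vals = codes[ok].ravel()
            if shuffle_copies_rng is not None:
                # copy-level shuffle within populations: breaks the pairing of
                # copies into individuals while keeping population totals
                pop_of_copy = np.repeat(pops_ind[ok], 2)
                vals = vals.copy()
                for p in np.unique(pop_of_copy):
                    sel = np.where(pop_of_copy == p)[0]
                    vals[sel] = vals[sel[shuffle_copies_rng.permutation(len(sel))]]
            labs = [np.repeat(lab[ok], 2) for lab in labels_per_ind]
            ss, df, sig = _amova_single_locus(vals, labs)
            tot_ss += ss
            tot_df += df
            tot_sig += sig
        return tot_ss, tot_df, tot_sig

    ss, df, sigma2 = run(labels_ind)
    total = sigma2.sum()
    pct = 100.0 * sigma2 / total if total != 0 else np.full_like(sigma2, np.nan)
    level_names = [f"between {hierarchy[0]}s"]
    for k in range(1, len(hierarchy)):
        level_names.append(f"between {hierarchy[k]}s within {hierarchy[k - 1]}s")
    level_names.append(f"between individuals within {hierarchy[-1]}s")
    level_names.append("within individuals")

    ncomp = len(sigma2)
    phi = {}
    phi["phi_IT"] = float(sigma2[:-1].sum() / total) if total else np.nan
    phi["phi_IS"] = (
        float(sigma2[-2] / (sigma2[-2] + sigma2[-1]))
        if (sigma2[-2] + sigma2[-1]) != 0
        else np.nan
    )
    phi["phi_ST"] = float(sigma2[:-2].sum() / total) if total else np.nan
    if ncomp == 4:
        phi["phi_CT"] = float(sigma2[0] / total) if total else np.nan
        phi["phi_SC"] = (
            float(sigma2[1] / sigma2[1:].sum()) if sigma2[1:].sum() != 0 else np.nan
        )

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = spawn_rng(seed, "amova")
        nlev = len(hierarchy)
        hits = np.zeros(len(sigma2))
        pops_arr = factor_values["population"]
        uniq_pops = gm.population_ids
        if nlev >= 2:
            pop_to_top = {
                p: factor_values[hierarchy[0]][np.where(pops_arr == p)[0][0]]
                for p in uniq_pops
            }
        for _ in range(n_perm):
            # scheme 1: whole populations permuted among top-level groups
            if nlev >= 2:
                shuffled_tops = rng.permutation([pop_to_top[p] for p in uniq_pops])
                top_map = dict(zip(uniq_pops, shuffled_tops))
                labs = [np.asarray([top_map[p] for p in pops_arr], dtype=object)]
                labs += labels_ind[1:]
                _, _, sig_p = run(labs)
                hits[0] += sig_p[0] >= sigma2[0] - 1e-12
            # scheme 2: individuals permuted among populations (within top group
            # when one exists, else globally)
            perm = np.arange(gm.n_individuals)
            if nlev >= 2:
                for g in np.unique(labels_ind[0]):
                    sel = np.where(labels_ind[0] == g)[0]
                    perm[sel] = sel[rng.permutation(len(sel))]
            else:
                perm = rng.permutation(gm.n_individuals)
            labs = list(labels_ind)
            labs[nlev - 1] = labels_ind[nlev - 1][perm]
            _, _, sig_p = run(labs)
            hits[nlev - 1] += sig_p[nlev - 1] >= sigma2[nlev - 1] - 1e-12
            # scheme 3: allele copies permuted among individuals within pops
            _, _, sig_p = run(labels_ind, shuffle_copies_rng=rng)
            hits[nlev] += sig_p[nlev] >= sigma2[nlev] - 1e-12
        for k, name in enumerate(level_names[:-1]):
            if nlev < 2 and k == 0 and len(level_names) > 3:
                continue
            p_values[name] = float((hits[k] + 1) / (n_perm + 1))

    return AmovaResult(
        levels=level_names,
        sigma2=sigma2,
        percentages=pct,
        phi=phi,
        ss=ss,
        df=df,
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Mantel / isolation by distance
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    exact: bool = False


def _mantel_r(x: np.ndarray, y: np.ndarray) -> float:
    iu = np.triu_indices(x.shape[0], k=1)
    a, b = x[iu], y[iu]
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    return float(a @ b) / denom if denom else np.nan


def mantel(
    x: DistanceMatrix | np.ndarray,
    y: DistanceMatrix | np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """One-sided Mantel test (H1: positive association).

    Permutes the labels of the second matrix.  ``exact=True`` enumerates all
    permutations (feasible for <= 7 labels) and reports the exact p-value.
    """
    xv = x.values if isinstance(x, DistanceMatrix) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, DistanceMatrix) else np.asarray(y, dtype=float)
    n = xv.shape[0]
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 labels")
    obs = _mantel_r(xv, yv)
    if exact:
        perms = list(itertools.permutations(range(n)))
        count = 0
        for p in perms:
            pv = yv[np.ix_(p, p)]
            if _mantel_r(xv, pv) >= obs - 1e-12:
                count += 1
        return MantelResult(obs, count / len(perms), len(perms), exact=True)
    rng = spawn_rng(seed, "mantel")
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _mantel_r(xv, yv[np.ix_(p, p)]) >= obs - 1e-12:
            hits += 1
    return MantelResult(obs, (hits + 1) / (n_perm + 1), n_perm)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in kilometres."""
    r = 6371.0088
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * r * math.asin(min(1.0, math.sqrt(h)))


def mantel_ibd(
    fst: DistanceMatrix,
    coords: Mapping[str, tuple[float, float]],
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Isolation by distance: FST/(1-FST) against log great-circle km.

    Coincident coordinates get a 1 km floor before the log transform.
    """
    missing = [p for p in fst.labels if p not in coords]
    if missing:
        raise ValidationError(f"populations without coordinates: {missing[:5]}")
    n = len(fst.labels)
    geo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(*coords[fst.labels[i]], *coords[fst.labels[j]])
            geo[i, j] = geo[j, i] = math.log(max(d, 1.0))
    f = np.clip(fst.values, 0.0, 0.999999)
    lin = f / (1.0 - f)
    return mantel(DistanceMatrix(fst.labels, lin, "linearised_fst"),
                  DistanceMatrix(fst.labels, geo, "geographic_log_km"),
                  n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# EM mixture clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    log_likelihood: float
    nu: int
    posteriors: np.ndarray
    mixing: np.ndarray
    frequencies: list[np.ndarray]
    assignments: np.ndarray
    converged: bool
    loglik_trace: list[float]

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.nu

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + self.nu * math.log(n)

    @property
    def kic(self) -> float:
        return -2.0 * self.log_likelihood + 3.0 * (self.nu + 1.0)


def _dosage_blocks(gm: GenotypeMatrix) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Per-locus dosage matrices, heterozygosity indicators and a combined
    standardised matrix for initialisation."""
    blocks = []
    hets = []
    for j in range(gm.n_loci):
        codes, sizes = gm.locus_codes(j)
        A = sizes.size
        D = np.zeros((gm.n_individuals, A))
        ok = codes[:, 0] >= 0
        idx = np.where(ok)[0]
        np.add.at(D, (idx, codes[idx, 0]), 1.0)
        np.add.at(D, (idx, codes[idx, 1]), 1.0)
        blocks.append(D)
        het = np.zeros(gm.n_individuals)
        het[idx] = (codes[idx, 0] != codes[idx, 1]).astype(float)
        hets.append(het)
    X = np.hstack(blocks)
    return blocks, hets, X


def _em_once(
    blocks: list[np.ndarray],
    hets: list[np.ndarray],
    resp0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, list[np.ndarray], bool, list[float]]:
    n, K = resp0.shape
    resp = resp0
    log2 = math.log(2.0)
    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    freqs: list[np.ndarray] = []
    mixing = np.full(K, 1.0 / K)
    for it in range(max_iter):
        # M-step from current responsibilities
        mixing = resp.mean(axis=0)
        if np.any(mixing < 1e-12):
            break  # empty cluster; caller restarts
        freqs = []
        for D in blocks:
            cnt = resp.T @ D  # (K, A) posterior-weighted allele counts
            tot = cnt.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(tot > 0, cnt / tot, 1.0 / max(D.shape[1], 1))
            freqs.append(f)
        # E-step
        logp = np.tile(np.log(mixing)[None, :], (n, 1))
        for D, het, f in zip(blocks, hets, freqs):
            logf = np.log(np.clip(f, 1e-300, None))
            logp += D @ logf.T + het[:, None] * log2
        mx = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - mx)
        tot = w.sum(axis=1, keepdims=True)
        resp = w / tot
        ll = float(np.sum(np.log(tot) + mx))
        trace.append(ll)
        if ll - ll_old < tol and it > 0:
            converged = True
            ll_old = max(ll, ll_old)
            break
        ll_old = ll
    return ll_old, resp, mixing, freqs, converged, trace


def em_cluster(
    gm: GenotypeMatrix,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterModel:
    """Maximum-likelihood mixture of HWE genotype models via EM.

    P(genotype | cluster) multiplies per-locus HWE terms (p^2 or 2pq) over
    typed loci.  Initialisation: k-means on leading principal components of
    the allele-dosage matrix, plus random restarts; best restart by logL.
    """
    if not 1 <= k <= gm.n_individuals:
        raise ValidationError("K must be in [1, n_individuals]")
    blocks, hets, X = _dosage_blocks(gm)
    n = gm.n_individuals
    rng = spawn_rng(seed, "em_cluster", str(k))

    if k == 1:
        resp0 = np.ones((n, 1))
        ll, resp, mixing, freqs, conv, trace = _em_once(blocks, hets, resp0, 2, tol)
        nu = sum(max(D.shape[1] - 1, 0) for D in blocks)
        return ClusterModel(1, ll, nu, resp, mixing, freqs, np.zeros(n, dtype=int), True, trace)

    inits: list[np.ndarray] = []
    # geometric init: k-means on PCs
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    npc = min(10, n - 1, X.shape[1])
    Z = PCA(n_components=npc, random_state=int(rng.integers(2**31))).fit_transform(
        X - X.mean(axis=0)
    )
    km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31))).fit(Z)
    resp = np.full((n, k), 0.01 / max(k - 1, 1))
    resp[np.arange(n), km.labels_] = 0.99
    inits.append(resp)
    # population-centroid init: cluster population mean profiles, then seed
    # individuals with their population's cluster (strong when sampling units
    # are internally homogeneous)
    pop_idx = gm.population_indices()
    if len(pop_idx) > k:
        from sklearn.cluster import AgglomerativeClustering

        cent = np.vstack([Z[rows].mean(axis=0) for rows in pop_idx.values()])
        seeds = [
            AgglomerativeClustering(n_clusters=k, linkage="ward").fit(cent).labels_,
            KMeans(n_clusters=k, n_init=3,
                   random_state=int(rng.integers(2**31))).fit(cent).labels_,
        ]
        for labels in seeds:
            lab_by_pop = dict(zip(pop_idx, labels))
            resp = np.full((n, k), 0.01 / max(k - 1, 1))
            for pid, rows in pop_idx.items():
                resp[rows, lab_by_pop[pid]] = 0.99
            inits.append(resp)
    for _ in range(max(0, n_restarts - len(inits))):
        r = rng.random((n, k)) + 1e-3
        inits.append(r / r.sum(axis=1, keepdims=True))

    best = None
    for resp0 in inits:
        ll, resp, mixing, freqs, conv, trace = _em_once(blocks, hets, resp0, max_iter, tol)
        if not freqs:
            continue
        if best is None or ll > best[0]:
            best = (ll, resp, mixing, freqs, conv, trace)
    if best is None:
        raise ValidationError(f"EM failed for K={k}: all restarts hit empty clusters")
    ll, resp, mixing, freqs, conv, trace = best
    nu = (k - 1) + k * sum(max(D.shape[1] - 1, 0) for D in blocks)
    return ClusterModel(
        k, ll, nu, resp, mixing, freqs, resp.argmax(axis=1), conv, trace
    )


def select_k(
    gm: GenotypeMatrix,
    k_range: Sequence[int],
    criterion: str = "KIC",
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[int, pd.DataFrame, dict[int, ClusterModel]]:
    """Scan K values, score each converged fit, return the argmin.

    KIC = -2 logL + 3 (nu + 1); ties break toward smaller K.
    """
    if criterion not in ("AIC", "BIC", "KIC"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    rows = []
    models: dict[int, ClusterModel] = {}
    for k in k_range:
        m = em_cluster(gm, k, n_restarts=n_restarts, seed=seed, max_iter=max_iter, tol=tol)
        models[k] = m
        rows.append(
            dict(
                K=k,
                logL=m.log_likelihood,
                nu=m.nu,
                AIC=m.aic,
                BIC=m.bic(gm.n_individuals),
                KIC=m.kic,
                converged=m.converged,
            )
        )
    table = pd.DataFrame(rows)
    usable = table[table.converged]
    if usable.empty:
        raise ValidationError("no K converged")
    best_k = int(usable.sort_values([criterion, "K"]).iloc[0].K)
    return best_k, table, models


# ---------------------------------------------------------------------------
# Hybrid classification
# ---------------------------------------------------------------------------

HYBRID_CLASSES = ("pure_A", "BC_A", "F1", "BC_B", "pure_B")
HYBRID_ALPHA = {"pure_A": 1.0, "BC_A": 0.75, "F1": 0.5, "BC_B": 0.25, "pure_B": 0.0}


@dataclass
class HybridClassResult:
    classes: tuple[str, ...]
    posteriors: pd.DataFrame
    assignments: pd.Series
    mixing: np.ndarray


def hybrid_classify(
    gm: GenotypeMatrix,
    parent_a: Sequence[int],
    parent_b: Sequence[int],
    query: Sequence[int],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> HybridClassResult:
    """Assign query individuals to pure, F1 and first-backcross classes.

    A class with parent-A ancestry alpha draws one allele copy from the
    gamete pool with frequency alpha-weighted toward parent A; the two copies
    of an individual come from the two parental-side gamete distributions of
    that class (e.g. F1: one A gamete, one B gamete).  Class proportions are
    fitted by EM; parental allele frequencies are estimated from the
    parental sets with Laplace smoothing.
    """
    pa = np.asarray(parent_a, dtype=np.intp)
    pb = np.asarray(parent_b, dtype=np.intp)
    q = np.asarray(query, dtype=np.intp)
    if np.intersect1d(pa, pb).size:
        raise ValidationError("parental sets must be disjoint")
    if len(pa) < 5 or len(pb) < 5:
        raise ValidationError("each parental set needs at least 5 individuals")

    # per-class gamete-source distributions (u, v) as mixtures of parents
    gamete_pairs = {
        "pure_A": (1.0, 1.0),
        "BC_A": (1.0, 0.5),
        "F1": (1.0, 0.0),
        "BC_B": (0.5, 0.0),
        "pure_B": (0.0, 0.0),
    }
    n_classes = len(HYBRID_CLASSES)
    logp = np.zeros((len(q), n_classes))
    used_loci = 0
    for j in range(gm.n_loci):
        codes, sizes = gm.locus_codes(j)
        A = sizes.size
        if A == 0:
            continue

        def freq(rows: np.ndarray) -> np.ndarray | None:
            sub = codes[rows]
            obs = sub[sub[:, 0] >= 0].ravel()
            if obs.size == 0:
                return None
            cnt = np.bincount(obs, minlength=A).astype(float) + 0.5
            return cnt / cnt.sum()

        fa, fb = freq(pa), freq(pb)
        if fa is None and fb is None:
            continue  # locus untyped in both parents: dropped
        if fa is None:
            fa = fb
        if fb is None:
            fb = fa
        used_loci += 1
        sub = codes[q]
        ok = sub[:, 0] >= 0
        a1, a2 = sub[:, 0], sub[:, 1]
        for c, name in enumerate(HYBRID_CLASSES):
            wa, wb = gamete_pairs[name]
            u = wa * fa + (1 - wa) * fb
            v = wb * fa + (1 - wb) * fb
            pr = np.ones(len(q))
            pr[ok] = u[a1[ok]] * v[a2[ok]] + u[a2[ok]] * v[a1[ok]]
            same = ok & (a1 == a2)
            pr[same] /= 2.0
            logp[:, c] += np.log(np.clip(pr, 1e-300, None))
    if used_loci == 0:
        raise ValidationError("no locus typed in either parental set")

    mix = np.full(n_classes, 1.0 / n_classes)
    ll_old = -np.inf
    for _ in range(max_iter):
        lw = logp + np.log(mix)[None, :]
        mx = lw.max(axis=1, keepdims=True)
        w = np.exp(lw - mx)
        tot = w.sum(axis=1, keepdims=True)
        resp = w / tot
        ll = float(np.sum(np.log(tot) + mx))
        mix = np.clip(resp.mean(axis=0), 1e-12, None)
        mix /= mix.sum()
        if ll - ll_old < tol:
            break
        ll_old = ll
    ids = [gm.individuals[i] for i in q]
    post = pd.DataFrame(resp, index=ids, columns=list(HYBRID_CLASSES))
    assign = post.idxmax(axis=1)
    return HybridClassResult(HYBRID_CLASSES, post, assign, mix)


# ---------------------------------------------------------------------------
# Ordinations
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained: np.ndarray
    barycentres: pd.DataFrame | None = None
    n_pc: int | None = None
    cross_validation: pd.DataFrame | None = None
    group_assignment: pd.Series | None = None


def dapc(
    gm: GenotypeMatrix,
    groups: Sequence[str] | None = None,
    n_pc: int | None = None,
    n_da: int | None = None,
    seed: int | None = None,
    cv_grid: Sequence[int] | None = None,
) -> OrdinationResult:
    """Discriminant analysis of principal components of allele dosages.

    When ``n_pc`` is not given it is selected by stratified 90/10
    cross-validation maximising mean assignment success over a grid.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.decomposition import PCA
    from sklearn.model_selection import StratifiedShuffleSplit

    y = np.asarray(groups if groups is not None else gm.populations)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("DAPC needs at least 2 groups")
    _, _, X = _dosage_blocks(gm)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    n = X.shape[0]
    max_pc = min(n - classes.size, X.shape[1], n - 1)
    if n_pc is not None and n_pc > max_pc:
        raise ValidationError(f"n_pc must be < n_individuals - n_groups (max {max_pc})")
    rng = spawn_rng(seed, "dapc")
    pca = PCA(n_components=min(max_pc, X.shape[1]), random_state=int(rng.integers(2**31)))
    Z = pca.fit_transform(X)

    cv_table = None
    if n_pc is None:
        grid = list(cv_grid) if cv_grid is not None else sorted(
            {max(1, int(round(g))) for g in np.linspace(1, max_pc, num=min(8, max_pc))}
        )
        min_class = np.bincount(np.searchsorted(classes, y)).min()
        results = []
        splitter = StratifiedShuffleSplit(
            n_splits=10 if min_class >= 10 else 5,
            test_size=0.1 if min_class >= 10 else 0.34,
            random_state=int(rng.integers(2**31)),
        )
        for p in grid:
            accs = []
            for tr, te in splitter.split(Z, y):
                lda = LinearDiscriminantAnalysis()
                lda.fit(Z[tr, :p], y[tr])
                accs.append(float(np.mean(lda.predict(Z[te, :p]) == y[te])))
            results.append(dict(n_pc=p, success=float(np.mean(accs))))
        cv_table = pd.DataFrame(results)
        n_pc = int(cv_table.sort_values(["success", "n_pc"], ascending=[False, True]).iloc[0].n_pc)

    lda = LinearDiscriminantAnalysis(n_components=min(classes.size - 1, n_pc) if n_da is None else n_da)
    coords = lda.fit_transform(Z[:, :n_pc], y)
    ev = getattr(lda, "explained_variance_ratio_", np.array([]))
    coord_df = pd.DataFrame(
        coords,
        index=gm.individuals,
        columns=[f"LD{i + 1}" for i in range(coords.shape[1])],
    )
    assign = pd.Series(lda.predict(Z[:, :n_pc]), index=gm.individuals)
    return OrdinationResult(
        coordinates=coord_df,
        eigenvalues=ev,
        explained=ev,
        n_pc=n_pc,
        cross_validation=cv_table,
        group_assignment=assign,
    )


def fca(gm: GenotypeMatrix) -> OrdinationResult:
    """Correspondence analysis of the individual x allele dosage table.

    Population barycentres are the means of member coordinates; per-axis
    explained fractions are principal inertias over total inertia.
    """
    if gm.n_populations < 3:
        raise ValidationError("FCA needs at least 3 populations")
    _, _, X = _dosage_blocks(gm)
    keep = X.sum(axis=0) > 0
    X = X[:, keep]
    const = np.all(X == X[0, :], axis=0)
    X = X[:, ~const]
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep_ax = sv > 1e-12
    U, sv = U[:, keep_ax], sv[keep_ax]
    rows = (U * sv[None, :]) / np.sqrt(r)[:, None]
    inertia = sv**2
    explained = inertia / inertia.sum()
    coord_df = pd.DataFrame(
        rows[:, : min(10, rows.shape[1])],
        index=gm.individuals,
        columns=[f"CA{i + 1}" for i in range(min(10, rows.shape[1]))],
    )
    coord_df["population"] = list(gm.populations)
    bary = coord_df.groupby("population", sort=False).mean()
    return OrdinationResult(
        coordinates=coord_df.drop(columns="population"),
        eigenvalues=inertia,
        explained=explained,
        barycentres=bary,
    )
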