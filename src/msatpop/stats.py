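"""Allele frequencies, diversity, Weir–Cockerham F-statistics, HWE tests
and null-allele estimation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypeMatrix, ValidationError, spawn_rng

__all__ = [
    "FreqTable",
    "FStats",
    "HweResult",
    "NullAlleleEstimate",
    "allele_frequencies",
    "diversity_table",
    "rarefied_allelic_richness",
    "wc_fstats",
    "hwe_exact_test",
    "null_allele_estimate",
]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FreqTable:
    """Per-(group, locus) allele counts and frequencies.

    ``counts[j]`` is a ``(G, A_j)`` integer array of gene-copy counts for
    locus ``j`` over the ``A_j`` distinct alleles observed dataset-wide at
    that locus (sizes in ``allele_sizes[j]``).  ``gene_counts`` is ``(G, L)``.
    """

    groups: list[str]
    allele_sizes: list[np.ndarray]
    counts: list[np.ndarray]
    gene_counts: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_loci(self) -> int:
        return len(self.counts)

    def frequencies(self, j: int) -> np.ndarray:
        """(G, A_j) frequencies; rows with zero gene count are all-NaN."""
        c = self.counts[j].astype(float)
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c / tot, np.nan)

    def empty_cells(self) -> list[tuple[str, int]]:
        """Cells (group, locus index) with zero non-missing gene copies."""
        out = []
        for g in range(self.n_groups):
            for j in range(self.n_loci):
                if self.gene_counts[g, j] == 0:
                    out.append((self.groups[g], j))
        return out

    def pooled(self) -> "FreqTable":
        """Collapse all groups into a single pooled group."""
        return FreqTable(
            groups=["pooled"],
            allele_sizes=self.allele_sizes,
            counts=[c.sum(axis=0, keepdims=True) for c in self.counts],
            gene_counts=self.gene_counts.sum(axis=0, keepdims=True),
        )


def _resolve_grouping(
    gm: GenotypeMatrix, grouping: Mapping[str, Sequence[int]] | None
) -> dict[str, np.ndarray]:
    if grouping is None:
        return gm.population_indices()
    cover = np.concatenate([np.asarray(v, dtype=np.intp) for v in grouping.values()])
    if np.unique(cover).size != gm.n_individuals:
        raise ValidationError("grouping must partition all individuals")
    return {k: np.asarray(v, dtype=np.intp) for k, v in grouping.items()}


def allele_frequencies(
    gm: GenotypeMatrix, grouping: Mapping[str, Sequence[int]] | None = None
) -> FreqTable:
    """Count gene copies per (group, locus) from non-missing calls only.

    ``grouping`` maps group label -> row indices; default is by population.
    """
    groups = _resolve_grouping(gm, grouping)
    labels = list(groups)
    G = len(labels)
    counts: list[np.ndarray] = []
    sizes_all: list[np.ndarray] = []
    gene_counts = np.zeros((G, gm.n_loci), dtype=np.int64)
    for j in range(gm.n_loci):
        codes, sizes = gm.locus_codes(j)
        A = sizes.size
        cj = np.zeros((G, max(A, 1)), dtype=np.int64)
        for g, lab in enumerate(labels):
            sub = codes[groups[lab]].ravel()
            sub = sub[sub >= 0]
            if sub.size:
                cj[g, : A] = np.bincount(sub, minlength=A)
            gene_counts[g, j] = sub.size
        counts.append(cj if A else np.zeros((G, 0), dtype=np.int64))
        sizes_all.append(sizes)
    return FreqTable(labels, sizes_all, counts, gene_counts)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


def _unbiased_he(freqs: np.ndarray, gene_count: float) -> float:
    """Nei's unbiased expected heterozygosity for one cell."""
    if gene_count < 2:
        return np.nan
    h = 1.0 - float(np.sum(freqs**2))
    return gene_count / (gene_count - 1.0) * h


def diversity_table(gm: GenotypeMatrix, freqs: FreqTable | None = None) -> pd.DataFrame:
    """Per-(population, locus) diversity: N_A, H_O, unbiased H_E, private
    allele counts.  Dataset-wide A_U (fraction of once-detected alleles) is
    attached per locus via the ``A_U`` column (same value for every group)."""
    if freqs is None:
        freqs = allele_frequencies(gm)
    groups = _resolve_grouping(gm, None)
    if list(groups) != freqs.groups:
        # diversity also needs genotype-level H_O, so grouping must align
        groups = {g: groups.get(g) for g in freqs.groups}
        if any(v is None for v in groups.values()):
            raise ValidationError("freqs grouping does not match populations")
    rows = []
    for j in range(gm.n_loci):
        codes, _ = gm.locus_codes(j)
        cj = freqs.counts[j]
        pooled = cj.sum(axis=0)
        n_pops_with = (cj > 0).sum(axis=0)
        a_u = float(np.mean(pooled[pooled > 0] == 1)) if (pooled > 0).any() else np.nan
        fj = freqs.frequencies(j)
        for g, lab in enumerate(freqs.groups):
            idx = groups[lab]
            sub = codes[idx]
            ok = sub[:, 0] >= 0
            n_geno = int(ok.sum())
            gc = int(freqs.gene_counts[g, j])
            n_a = int((cj[g] > 0).sum())
            if n_geno == 0:
                ho = np.nan
            else:
                ho = float(np.mean(sub[ok, 0] != sub[ok, 1]))
            he = _unbiased_he(fj[g][~np.isnan(fj[g])], gc) if gc >= 2 else np.nan
            private = int(np.sum((cj[g] > 0) & (n_pops_with == 1)))
            rows.append(
                dict(
                    population=lab,
                    locus=gm.loci[j].name,
                    gene_count=gc,
                    N_A=n_a,
                    H_O=ho,
                    H_E=he,
                    A_U=a_u,
                    private_alleles=private,
                )
            )
    return pd.DataFrame(rows)


def rarefied_allelic_richness(
    gm: GenotypeMatrix, g: int = 10, freqs: FreqTable | None = None
) -> pd.DataFrame:
    """Hypergeometric rarefied allelic richness per (population, locus).

    A_R = sum_a [1 - C(N - N_a, g) / C(N, g)] with N the cell's gene count
    and N_a the copies of allele a.  Raises when any cell has fewer than
    ``g`` gene copies (cells listed in the error).
    """
    if freqs is None:
        freqs = allele_frequencies(gm)
    short = [
        (freqs.groups[gg], gm.loci[j].name)
        for gg in range(freqs.n_groups)
        for j in range(freqs.n_loci)
        if freqs.gene_counts[gg, j] < g
    ]
    if short:
        raise ValidationError(
            f"gene count below rarefaction size g={g} in cells: {short[:10]}"
            + ("..." if len(short) > 10 else "")
        )
    rows = []
    for j in range(freqs.n_loci):
        cj = freqs.counts[j]
        N = cj.sum(axis=1)
        for gg, lab in enumerate(freqs.groups):
            counts = cj[gg][cj[gg] > 0]
            ar = float(np.sum(1.0 - _hyper_miss(N[gg], counts, g)))
            rows.append(dict(population=lab, locus=gm.loci[j].name, A_R=ar))
    return pd.DataFrame(rows)


def _hyper_miss(N: int, counts: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a draw of g copies) = C(N-N_a, g)/C(N, g)."""
    out = np.zeros(len(counts))
    rem = N - counts
    ok = rem >= g
    if ok.any():
        num = gammaln(rem[ok] + 1) - gammaln(g + 1) - gammaln(rem[ok] - g + 1)
        den = gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
        out[ok] = np.exp(num - den)
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham F-statistics
# ---------------------------------------------------------------------------


@dataclass
class FStats:
    """Variance components and fixation indices, per locus and overall."""

    per_locus: pd.DataFrame
    fst: float
    fis: float
    fit: float
    p_fst: float | None = None
    components: dict = field(default_factory=dict)


def _wc_components_locus(
    codes: np.ndarray, group_rows: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    """Summed a, b, c over alleles for one locus.

    ``codes``: (n, 2) allele indices (-1 missing); groups with no data at the
    locus are dropped.
    """
    per_pop = []
    for rows in group_rows:
        sub = codes[rows]
        ok = sub[:, 0] >= 0
        if ok.sum() >= 1:
            per_pop.append(sub[ok])
    r = len(per_pop)
    if r < 2:
        return 0.0, 0.0, 0.0
    A = int(codes.max()) + 1
    n_i = np.array([len(s) for s in per_pop], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    n_c = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    # per-allele frequencies and heterozygote proportions
    p = np.zeros((r, A))
    h = np.zeros((r, A))
    for i, s in enumerate(per_pop):
        cnt = np.bincount(s.ravel(), minlength=A)
        p[i] = cnt / (2 * len(s))
        het = s[:, 0] != s[:, 1]
        for a in range(A):
            h[i, a] = np.mean(het & ((s[:, 0] == a) | (s[:, 1] == a)))
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h).sum(axis=0) / (r * nbar)
    if n_c <= 0:
        return 0.0, 0.0, 0.0
    term = pbar * (1 - pbar) - (r - 1) / r * s2
    a_comp = nbar / n_c * (s2 - (term - hbar / 4.0) / (nbar - 1))
    b_comp = nbar / (nbar - 1) * (term - (2 * nbar - 1) / (4 * nbar) * hbar)
    c_comp = hbar / 2.0
    return float(a_comp.sum()), float(b_comp.sum()), float(c_comp.sum())


def wc_fstats(
    gm: GenotypeMatrix,
    grouping: Mapping[str, Sequence[int]] | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> FStats:
    """Weir–Cockerham (1984) F-statistics combined by ratio of sums.

    Components are summed per allele within loci and across loci; the overall
    F_ST is Σa / Σ(a+b+c), F_IS is 1 − Σc/Σ(b+c), F_IT is 1 − Σc/Σ(a+b+c).
    Optional significance for F_ST by permuting individuals among groups.
    """
    groups = _resolve_grouping(gm, grouping)
    if len(groups) < 2:
        raise ValidationError("F_ST undefined for a single group")
    group_rows = list(groups.values())

    def compute(rows_list):
        A = B = C = 0.0
        per_locus = []
        for j in range(gm.n_loci):
            codes, _ = gm.locus_codes(j)
            a, b, c = _wc_components_locus(codes, rows_list)
            per_locus.append((gm.loci[j].name, a, b, c))
            A, B, C = A + a, B + b, C + c
        return A, B, C, per_locus

    A, B, C, per_locus = compute(group_rows)

    def safe_div(x, y):
        return x / y if y != 0 else np.nan

    rows = []
    for name, a, b, c in per_locus:
        rows.append(
            dict(
                locus=name,
                a=a,
                b=b,
                c=c,
                fst=safe_div(a, a + b + c),
                fis=1 - safe_div(c, b + c),
                fit=1 - safe_div(c, a + b + c),
            )
        )
    fst = safe_div(A, A + B + C)
    fis = 1 - safe_div(C, B + C)
    fit = 1 - safe_div(C, A + B + C)

    p_fst = None
    if n_perm > 0:
        rng = spawn_rng(seed, "wc_fstats")
        sizes = [len(r) for r in group_rows]
        pool = np.concatenate(group_rows)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            split = np.split(perm, np.cumsum(sizes)[:-1])
            Ap, Bp, Cp, _ = compute(split)
            if safe_div(Ap, Ap + Bp + Cp) >= fst - 1e-12:
                hits += 1
        p_fst = (hits + 1) / (n_perm + 1)

    return FStats(
        per_locus=pd.DataFrame(rows),
        fst=float(fst),
        fis=float(fis),
        fit=float(fit),
        p_fst=p_fst,
        components={"a": A, "b": B, "c": C},
    )


# ---------------------------------------------------------------------------
# HWE exact test (Monte Carlo)
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    population: str
    locus: str
    p_value: float
    n_permutations: int
    seed: int | None


def _genotype_log_prob(pair_codes: np.ndarray, n_alleles: int) -> np.ndarray:
    """Log conditional probability of genotype arrays given allele counts.

    ``pair_codes``: (m, n) sorted-pair codes a*A+b per individual, for m
    candidate arrays over the same multiset of 2n gene copies.  The terms
    constant across arrays (allele-count factorials, (2n)!) are dropped.
    """
    m, n = pair_codes.shape
    ncodes = n_alleles * n_alleles
    counts = np.zeros((m, ncodes), dtype=np.int64)
    rows = np.repeat(np.arange(m), n)
    np.add.at(counts, (rows, pair_codes.ravel()), 1)
    a_idx = np.arange(ncodes) // n_alleles
    b_idx = np.arange(ncodes) % n_alleles
    het = (a_idx != b_idx).astype(float)
    n_het = counts @ het
    return n_het * np.log(2.0) - gammaln(counts + 1).sum(axis=1)


def hwe_exact_test(
    gm: GenotypeMatrix,
    population: str,
    locus: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> HweResult:
    """Monte-Carlo exact test of Hardy–Weinberg proportions for one cell.

    Gene copies are repeatedly shuffled into random diploid pairings; the
    p-value is the proportion of arrays (observed included) whose conditional
    probability is at most the observed array's.
    """
    j = [l.name for l in gm.loci].index(locus)
    rows = gm.population_indices()[population]
    codes, sizes = gm.locus_codes(j)
    sub = codes[rows]
    sub = sub[sub[:, 0] >= 0]
    if len(sub) < 2:
        raise ValidationError(f"{population}/{locus}: fewer than 2 genotyped individuals")
    present = np.unique(sub.ravel())
    if present.size < 2:
        return HweResult(population, locus, 1.0, n_perm, seed)
    # re-index to compact codes
    remap = np.searchsorted(present, sub)
    A = present.size
    n = len(remap)
    obs_pairs = (np.minimum(remap[:, 0], remap[:, 1]) * A + np.maximum(remap[:, 0], remap[:, 1]))[None, :]
    logp_obs = _genotype_log_prob(obs_pairs, A)[0]

    rng = spawn_rng(seed, "hwe", population, locus)
    copies = remap.ravel()
    # vectorised shuffles: argsort of uniform keys per permutation
    batch = min(n_perm, 2000)
    hits = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, 2 * n))
        order = np.argsort(keys, axis=1)
        shuffled = copies[order]
        a = shuffled[:, 0::2]
        bb = shuffled[:, 1::2]
        pairs = np.minimum(a, bb) * A + np.maximum(a, bb)
        logp = _genotype_log_prob(pairs, A)
        hits += int(np.sum(logp <= logp_obs + 1e-9))
        done += b
    p = (hits + 1) / (n_perm + 1)
    return HweResult(population, locus, float(p), n_perm, seed)


def hwe_table(
    gm: GenotypeMatrix, n_perm: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """HWE tests for every (population, locus) cell with >=2 genotypes.

    Includes Bonferroni significance within population across its locus
    tests (alpha 0.05 / number of testable loci in that population)."""
    rows = []
    for pid in gm.population_ids:
        cell_results = []
        for locus in gm.loci:
            try:
                r = hwe_exact_test(gm, pid, locus.name, n_perm=n_perm, seed=seed)
            except ValidationError:
                continue
            cell_results.append(r)
        k = len(cell_results)
        for r in cell_results:
            rows.append(
                dict(
                    population=r.population,
                    locus=r.locus,
                    p_value=r.p_value,
                    significant=bool(k and r.p_value < 0.05 / k),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Null alleles (Brookfield)
# ---------------------------------------------------------------------------


@dataclass
class NullAlleleEstimate:
    population: str
    locus: str
    r1_raw: float
    r1: float
    r2_raw: float
    r2: float
    ci_low: float | None
    ci_high: float | None
    significant: bool | None


def brookfield1(h_e: float, h_o: float) -> float:
    """Estimator 1: r = (H_E - H_O) / (1 + H_E)."""
    return (h_e - h_o) / (1.0 + h_e)


def brookfield2(h_e: float, h_o: float, beta: float) -> float:
    """Estimator 2 adds observed non-amplifying individuals (frequency
    ``beta``) treated as null homozygotes; coincides with estimator 1 at
    beta = 0."""
    return (h_e - h_o + 2.0 * beta) / (1.0 + h_e + 2.0 * beta)


def null_allele_estimate(
    gm: GenotypeMatrix,
    population: str,
    locus: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> NullAlleleEstimate:
    """Brookfield null-allele frequency estimates with a bootstrap CI.

    Bootstrap resamples individuals; significance means the 95% CI of the
    estimator-2 value excludes zero.  Raw values may be negative; the
    truncated value max(0, raw) is reported alongside.
    """
    j = [l.name for l in gm.loci].index(locus)
    rows = gm.population_indices()[population]
    codes, _ = gm.locus_codes(j)
    sub = codes[rows]

    def estimates(s: np.ndarray) -> tuple[float, float]:
        ok = s[:, 0] >= 0
        typed = s[ok]
        if len(typed) < 2:
            return np.nan, np.nan
        beta = float(np.mean(~ok))
        cnt = np.bincount(typed.ravel())
        p = cnt / float(typed.size)  # typed.size == 2 * n_typed gene copies
        he = _unbiased_he(p[p > 0], typed.size)
        ho = float(np.mean(typed[:, 0] != typed[:, 1]))
        return brookfield1(he, ho), brookfield2(he, ho, beta)

    r1_raw, r2_raw = estimates(sub)
    if sub[sub[:, 0] >= 0].shape[0] * 2 < 4:
        return NullAlleleEstimate(
            population, locus, r1_raw, max(0.0, r1_raw), r2_raw, max(0.0, r2_raw),
            None, None, None,
        )
    rng = spawn_rng(seed, "brookfield", population, locus)
    boots = np.empty(n_boot)
    n = len(sub)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        boots[b] = estimates(sub[take])[1]
    boots = boots[~np.isnan(boots)]
    if boots.size < 10:
        lo = hi = None
        sig = None
    else:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        sig = bool(lo > 0.0 or hi < 0.0)
    return NullAlleleEstimate(
        population, locus, float(r1_raw), max(0.0, float(r1_raw)),
        float(r2_raw), max(0.0, float(r2_raw)),
        None if lo is None else float(lo), None if hi is None else float(hi), sig,
    )
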