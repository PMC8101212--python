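"""Two-locus linkage disequilibrium: per-population likelihood-ratio tests,
Ohta's variance decomposition across populations, and LD-based effective
population size.

All estimators are phase-free: the likelihood-ratio test integrates over
phase with an EM haplotype-frequency fit, while Ohta components and Ne use
Burrows composite disequilibrium from genotype dosages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .types import GenotypeMatrix, ValidationError, spawn_rng

__all__ = [
    "LDTestResult",
    "OhtaD",
    "NeEstimate",
    "ld_test",
    "ld_test_all",
    "ohta_components",
    "ne_ld",
]


# ---------------------------------------------------------------------------
# EM likelihood-ratio LD test
# ---------------------------------------------------------------------------


@dataclass
class LDTestResult:
    population: str
    locus_pair: tuple[str, str]
    statistic: float
    p_value: float | None
    n_perm: int
    seed: int | None


def _em_loglik(a1, a2, b1, b2, A, B, max_iter=100, tol=1e-8):
    """EM over two-locus haplotype frequencies; returns (lnL_full, lnL_eq)."""
    n = len(a1)
    pa = np.bincount(np.concatenate([a1, a2]), minlength=A) / (2.0 * n)
    pb = np.bincount(np.concatenate([b1, b2]), minlength=B) / (2.0 * n)
    H = np.outer(pa, pb)
    mult = ((a1 != a2).astype(int) + (b1 != b2).astype(int) - 1).astype(float)
    log2mult = mult * np.log(2.0)

    def loglik(Hm):
        w1 = Hm[a1, b1] * Hm[a2, b2]
        w2 = Hm[a1, b2] * Hm[a2, b1]
        return float(np.sum(np.log(np.maximum(w1 + w2, 1e-300)) + log2mult))

    ll_eq = loglik(H)
    ll_old = ll_eq
    for _ in range(max_iter):
        w1 = H[a1, b1] * H[a2, b2]
        w2 = H[a1, b2] * H[a2, b1]
        tot = np.maximum(w1 + w2, 1e-300)
        f1 = w1 / tot
        f2 = 1.0 - f1
        Hn = np.zeros_like(H)
        np.add.at(Hn, (a1, b1), f1)
        np.add.at(Hn, (a2, b2), f1)
        np.add.at(Hn, (a1, b2), f2)
        np.add.at(Hn, (a2, b1), f2)
        H = Hn / (2.0 * n)
        ll = loglik(H)
        if ll - ll_old < tol:
            ll_old = max(ll, ll_old)
            break
        ll_old = ll
    return ll_old, ll_eq


def ld_test(
    gm: GenotypeMatrix,
    population: str,
    locus_pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> LDTestResult:
    """Genotypic LD likelihood-ratio test within one population.

    The statistic is 2*(lnL of EM haplotype frequencies - lnL under
    independence); the p-value permutes one locus's genotypes across
    individuals.  ``n_perm = 0`` returns the statistic with p = None.
    """
    names = [l.name for l in gm.loci]
    j1, j2 = names.index(locus_pair[0]), names.index(locus_pair[1])
    rows = gm.population_indices()[population]
    c1, _ = gm.locus_codes(j1)
    c2, _ = gm.locus_codes(j2)
    s1, s2 = c1[rows], c2[rows]
    ok = (s1[:, 0] >= 0) & (s2[:, 0] >= 0)
    s1, s2 = s1[ok], s2[ok]
    if len(s1) < 5:
        raise ValidationError(
            f"{population}/{locus_pair}: fewer than 5 doubly-genotyped individuals"
        )
    # compact allele codes within the cell
    u1 = np.unique(s1.ravel())
    u2 = np.unique(s2.ravel())
    a = np.searchsorted(u1, s1)
    b = np.searchsorted(u2, s2)
    if u1.size < 2 or u2.size < 2:
        return LDTestResult(population, locus_pair, 0.0, 1.0 if n_perm else None, n_perm, seed)
    A, B = u1.size, u2.size
    ll_full, ll_eq = _em_loglik(a[:, 0], a[:, 1], b[:, 0], b[:, 1], A, B)
    stat = max(0.0, 2.0 * (ll_full - ll_eq))
    if n_perm == 0:
        return LDTestResult(population, locus_pair, stat, None, 0, seed)
    rng = spawn_rng(seed, "ld_test", population, *locus_pair)
    hits = 0
    n = len(a)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[perm]
        llf, lle = _em_loglik(a[:, 0], a[:, 1], bp[:, 0], bp[:, 1], A, B)
        if max(0.0, 2.0 * (llf - lle)) >= stat - 1e-9:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return LDTestResult(population, locus_pair, stat, float(p), n_perm, seed)


def ld_test_all(
    gm: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Run the LD test for every locus pair in every population.

    Cells with fewer than ``min_n`` doubly-genotyped individuals are still
    enumerated (statistic NaN) so the test count matches the study design.
    """
    names = [l.name for l in gm.loci]
    rows = []
    for pid in gm.population_ids:
        for l1, l2 in combinations(names, 2):
            try:
                r = ld_test(gm, pid, (l1, l2), n_perm=n_perm, seed=seed)
                rows.append(
                    dict(population=pid, locus_1=l1, locus_2=l2,
                         statistic=r.statistic, p_value=r.p_value)
                )
            except ValidationError:
                rows.append(
                    dict(population=pid, locus_1=l1, locus_2=l2,
                         statistic=np.nan, p_value=np.nan)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ohta's D-statistics
# ---------------------------------------------------------------------------


@dataclass
class OhtaD:
    locus_pair: tuple[str, str]
    d2_is: float
    d2_st: float
    dp2_is: float
    dp2_st: float
    d2_it: float

    @property
    def ratio_st_is(self) -> float:
        return self.d2_st / self.d2_is if self.d2_is > 0 else np.nan

    @property
    def ratio_st_is_primed(self) -> float:
        return self.dp2_st / self.dp2_is if self.dp2_is > 0 else np.nan

    @property
    def log_ratio(self) -> float:
        r = self.ratio_st_is
        return float(np.log(r)) if r and r > 0 else np.nan


def _dosage(codes: np.ndarray, A: int) -> np.ndarray:
    """(n, A) allele dosage matrix from (n, 2) codes; missing rows are zero."""
    n = codes.shape[0]
    D = np.zeros((n, A))
    ok = codes[:, 0] >= 0
    idx = np.where(ok)[0]
    np.add.at(D, (idx, codes[idx, 0]), 1.0)
    np.add.at(D, (idx, codes[idx, 1]), 1.0)
    return D


def ohta_components(
    gm: GenotypeMatrix,
    locus_pair: tuple[str, str],
    grouping: Mapping[str, Sequence[int]] | None = None,
) -> OhtaD:
    """Ohta's decomposition of squared LD within and between populations.

    Composite "gamete" frequencies g_ijk come from Burrows estimates on
    unphased genotypes; all averages over populations are unweighted, which
    makes the identity D2_IT = D'2_IS + D'2_ST exact.
    """
    names = [l.name for l in gm.loci]
    j1, j2 = names.index(locus_pair[0]), names.index(locus_pair[1])
    groups = (
        gm.population_indices()
        if grouping is None
        else {k: np.asarray(v, dtype=np.intp) for k, v in grouping.items()}
    )
    c1, u1 = gm.locus_codes(j1)
    c2, u2 = gm.locus_codes(j2)
    A, B = u1.size, u2.size
    gs, xs, ys = [], [], []
    for rows in groups.values():
        s1, s2 = c1[rows], c2[rows]
        ok = (s1[:, 0] >= 0) & (s2[:, 0] >= 0)
        n = int(ok.sum())
        if n < 2:
            continue
        D1 = _dosage(s1[ok], A)
        D2 = _dosage(s2[ok], B)
        g = D1.T @ D2 / (4.0 * n)
        xs.append(D1.sum(axis=0) / (2.0 * n))
        ys.append(D2.sum(axis=0) / (2.0 * n))
        gs.append(g)
    K = len(gs)
    if K == 0:
        raise ValidationError(f"{locus_pair}: no population with usable data")
    g = np.stack(gs)            # (K, A, B)
    x = np.stack(xs)            # (K, A)
    y = np.stack(ys)            # (K, B)
    xy = x[:, :, None] * y[:, None, :]
    gbar = g.mean(axis=0)
    xbar_ybar = x.mean(axis=0)[:, None] * y.mean(axis=0)[None, :]
    d2_is = float(np.mean(np.sum((g - xy) ** 2, axis=(1, 2))))
    d2_st = float(np.mean(np.sum((xy - xbar_ybar) ** 2, axis=(1, 2))))
    dp2_is = float(np.mean(np.sum((g - gbar) ** 2, axis=(1, 2))))
    dp2_st = float(np.sum((gbar - xbar_ybar) ** 2))
    d2_it = float(np.mean(np.sum((g - xbar_ybar) ** 2, axis=(1, 2))))
    # at K == 1, D2_ST is identically 0 (xy equals its mean); Dp2_ST then
    # degenerates to D2_IT, keeping the decomposition identity exact
    return OhtaD(locus_pair, d2_is, d2_st, dp2_is, dp2_st, d2_it)


def ohta_table(gm: GenotypeMatrix, grouping=None) -> pd.DataFrame:
    rows = []
    names = [l.name for l in gm.loci]
    for l1, l2 in combinations(names, 2):
        o = ohta_components(gm, (l1, l2), grouping)
        rows.append(
            dict(locus_1=l1, locus_2=l2, D2_IS=o.d2_is, D2_ST=o.d2_st,
                 Dp2_IS=o.dp2_is, Dp2_ST=o.dp2_st, D2_IT=o.d2_it,
                 ratio_ST_IS=o.ratio_st_is, log_ratio=o.log_ratio)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------


@dataclass
class NeEstimate:
    population: str
    r2_mean: float
    r2_drift: float
    ne_point: float
    ci: tuple[float, float]
    n_comparisons: int
    harmonic_s: float
    crit: str
    mating: str
    low_confidence: bool = False


def _expected_r2_sample(s: float) -> float:
    # Waples (2006) sampling expectation; S >= 30 regime, small-S branch below
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 1.0 / s + 0.69 / s**2


def _ne_from_r2drift(r2d: float, mating: str) -> float:
    if r2d <= 0:
        return np.inf
    if mating == "monogamy":
        disc = max(0.0, 4.0 / 9.0 - 7.2 * r2d)
        return (2.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)
    disc = max(0.0, 1.0 / 9.0 - 2.76 * r2d)
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)


def ne_ld(
    gm: GenotypeMatrix,
    population: str,
    crit: str = "singletons",
    mating: str = "monogamy",
) -> NeEstimate:
    """LD effective population size from Burrows composite correlations.

    ``crit='singletons'`` drops alleles seen exactly once in the population
    (``'none'`` keeps everything).  ``mating`` selects the monogamy or
    random-mating bias correction of the drift-LD relation.
    """
    if mating not in ("monogamy", "random"):
        raise ValidationError(f"unknown mating system {mating!r}")
    rows = gm.population_indices()[population]
    r2s: list[float] = []
    ns: list[int] = []
    polymorphic = 0
    per_locus: list[tuple[np.ndarray, np.ndarray]] = []  # (codes, kept allele codes)
    for j in range(gm.n_loci):
        codes, _ = gm.locus_codes(j)
        sub = codes[rows]
        obs = sub[sub[:, 0] >= 0].ravel()
        if obs.size == 0:
            per_locus.append((sub, np.array([], dtype=int)))
            continue
        cnt = np.bincount(obs)
        keep = np.where(cnt >= (2 if crit == "singletons" else 1))[0]
        if keep.size >= 2:
            polymorphic += 1
        per_locus.append((sub, keep))
    if polymorphic < 2:
        raise ValidationError(f"{population}: fewer than 2 polymorphic loci after exclusions")

    for j1, j2 in combinations(range(gm.n_loci), 2):
        s1, k1 = per_locus[j1]
        s2, k2 = per_locus[j2]
        if k1.size < 2 or k2.size < 2:
            continue
        ok = (s1[:, 0] >= 0) & (s2[:, 0] >= 0)
        n = int(ok.sum())
        if n < 3:
            continue
        D1 = _dosage(s1[ok], int(s1.max()) + 1)[:, k1]
        D2 = _dosage(s2[ok], int(s2.max()) + 1)[:, k2]
        p = D1.mean(axis=0) / 2.0
        q = D2.mean(axis=0) / 2.0
        usable1 = (p > 0) & (p < 1)
        usable2 = (q > 0) & (q < 1)
        if not usable1.any() or not usable2.any():
            continue
        G = D1[:, usable1].T @ D2[:, usable2] / (2.0 * n)
        delta = (G - 2.0 * np.outer(p[usable1], q[usable2])) * n / (n - 1.0)
        denom = np.outer(p[usable1] * (1 - p[usable1]), q[usable2] * (1 - q[usable2]))
        r2 = delta**2 / denom
        r2s.extend(r2.ravel().tolist())
        ns.extend([n] * r2.size)
    if not r2s:
        raise ValidationError(f"{population}: no usable locus-pair comparisons")
    r2s_arr = np.asarray(r2s)
    ns_arr = np.asarray(ns, dtype=float)
    r2_mean = float(np.mean(r2s_arr))
    harmonic_s = float(len(ns_arr) / np.sum(1.0 / ns_arr))
    r2_drift = r2_mean - _expected_r2_sample(harmonic_s)
    ne = _ne_from_r2drift(r2_drift, mating)
    df = len(r2s_arr)
    lo_r2 = r2_mean * df / chi2.ppf(0.975, df)
    hi_r2 = r2_mean * df / chi2.ppf(0.025, df)
    ci_hi = _ne_from_r2drift(lo_r2 - _expected_r2_sample(harmonic_s), mating)
    ci_lo = _ne_from_r2drift(hi_r2 - _expected_r2_sample(harmonic_s), mating)
    return NeEstimate(
        population=population,
        r2_mean=r2_mean,
        r2_drift=float(r2_drift),
        ne_point=float(ne),
        ci=(float(ci_lo), float(ci_hi)),
        n_comparisons=df,
        harmonic_s=harmonic_s,
        crit=crit,
        mating=mating,
        low_confidence=harmonic_s < 10,
    )
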