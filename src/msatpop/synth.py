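"""Labelled synthetic microsatellite datasets with known truth.

Two generator families:

* fast Dirichlet-drift generators (island worlds, hybrid panels, forward
  bottleneck strains) for testing the statistics stack, and
* the coalescent-backed generators in :mod:`msatpop.coalescent` for ABC.

Both emit the same :class:`~msatpop.types.GenotypeMatrix`, plus a
:class:`TruthRecord` sufficient to re-create the dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (
    GenotypeMatrix,
    LocusDef,
    PopulationMetadata,
    SUBCONTINENTS,
    ValidationError,
    spawn_rng,
)

__all__ = [
    "TruthRecord",
    "SyntheticWorldConfig",
    "default_loci",
    "make_island_world",
    "make_hybrid_panel",
    "make_domesticated_bottleneck",
    "make_global_fixture",
]


@dataclass
class TruthRecord:
    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"generator": self.generator, "seed": self.seed, "params": self.params}


# allele-count profile of the emulated 15-marker panel (dataset-wide targets)
DEFAULT_ALLELE_COUNTS = (29, 36, 31, 30, 17, 12, 25, 19, 31, 8, 30, 28, 24, 32, 16)


def default_loci(n_loci: int = 15) -> list[LocusDef]:
    """Di-/trinucleotide loci with realistic, non-overlapping size supports."""
    loci = []
    for j in range(n_loci):
        motif = 2 if j % 3 != 2 else 3
        lo = 90 + 20 * j
        hi = lo + motif * 48 + 6
        loci.append(LocusDef(name=f"loc{j + 1:02d}", motif_length=motif,
                             size_range=(lo, hi), missing_code=0))
    return loci


def _allele_sizes(locus: LocusDef, n_alleles: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = locus.size_range
    lattice = np.arange(lo + 2, hi - 2, locus.motif_length)
    if n_alleles > lattice.size:
        n_alleles = lattice.size
    return np.sort(rng.choice(lattice, size=n_alleles, replace=False))


def _hwe_genotypes(
    freqs: np.ndarray, sizes: np.ndarray, n: int, rng: np.random.Generator,
    fis: float = 0.0,
) -> np.ndarray:
    """Diploid draws; with inbreeding coefficient ``fis`` the second copy is
    identical by descent with that probability."""
    copies = rng.choice(sizes, size=(n, 2), p=freqs)
    if fis > 0:
        ibd = rng.random(n) < fis
        copies[ibd, 1] = copies[ibd, 0]
    return np.sort(copies, axis=1)


def _deme_freqs(ancestral: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return ancestral.copy()
    alpha = ancestral * (1.0 - fst) / fst
    return rng.dirichlet(np.clip(alpha, 1e-6, None))


def make_island_world(
    k_demes: int,
    n_per_deme: int | Sequence[int],
    loci: Sequence[LocusDef] | None = None,
    target_fst: float = 0.2,
    n_alleles: int = 12,
    dirichlet_alpha: float = 1.0,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Island-model world: deme allele frequencies are Dirichlet-perturbed
    copies of a common ancestral frequency vector with E[FST] near target.
    """
    if not 0.0 <= target_fst < 0.9:
        raise ValidationError("target_fst must be in [0, 0.9)")
    rng = spawn_rng(seed, "island_world")
    loci = list(loci) if loci is not None else default_loci()
    sizes_n = (
        [n_per_deme] * k_demes if np.isscalar(n_per_deme) else list(n_per_deme)
    )
    n_total = int(sum(sizes_n))
    calls = np.zeros((n_total, len(loci), 2), dtype=np.int64)
    deme_labels = np.concatenate(
        [np.full(s, f"deme_{d + 1}", dtype=object) for d, s in enumerate(sizes_n)]
    )
    for j, locus in enumerate(loci):
        sizes = _allele_sizes(locus, n_alleles, rng)
        if sizes.size < 2 and target_fst > 0:
            import warnings

            warnings.warn(f"locus {locus.name}: <2 alleles, FST target infeasible")
        anc = rng.dirichlet(np.full(sizes.size, dirichlet_alpha))
        start = 0
        for d, s in enumerate(sizes_n):
            f = _deme_freqs(anc, target_fst, rng)
            calls[start:start + s, j, :] = _hwe_genotypes(f, sizes, s, rng)
            start += s
    individuals = [f"ind_{i + 1}" for i in range(n_total)]
    gm = GenotypeMatrix(individuals, loci, calls, deme_labels)
    truth = TruthRecord(
        "island_world",
        seed,
        dict(k_demes=k_demes, n_per_deme=sizes_n, target_fst=target_fst,
             n_alleles=n_alleles, true_deme={ind: str(d) for ind, d in zip(individuals, deme_labels)}),
    )
    return gm, truth


def make_hybrid_panel(
    parent_fst: float,
    n_pure: int = 30,
    n_f1: int = 30,
    n_bc: int = 30,
    loci: Sequence[LocusDef] | None = None,
    n_alleles: int = 12,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Two diverged parental demes plus F1 and first-backcross individuals.

    F1: one gamete from each parent pool.  Backcross: one parental gamete
    plus one F1 gamete (an equal mixture of the parental pools per locus).
    """
    if parent_fst <= 0:
        raise ValidationError("parent_fst must be > 0")
    rng = spawn_rng(seed, "hybrid_panel")
    loci = list(loci) if loci is not None else default_loci()
    group_sizes = {
        "pure_A": n_pure, "pure_B": n_pure, "F1": n_f1, "BC_A": n_bc, "BC_B": n_bc,
    }
    labels = np.concatenate(
        [np.full(s, g, dtype=object) for g, s in group_sizes.items()]
    )
    n_total = len(labels)
    calls = np.zeros((n_total, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        sizes = _allele_sizes(locus, n_alleles, rng)
        anc = rng.dirichlet(np.ones(sizes.size))
        fa = _deme_freqs(anc, parent_fst, rng)
        fb = _deme_freqs(anc, parent_fst, rng)
        fmix = 0.5 * fa + 0.5 * fb
        start = 0
        for g, s in group_sizes.items():
            if g == "pure_A":
                geno = _hwe_genotypes(fa, sizes, s, rng)
            elif g == "pure_B":
                geno = _hwe_genotypes(fb, sizes, s, rng)
            elif g == "F1":
                a = rng.choice(sizes, size=s, p=fa)
                b = rng.choice(sizes, size=s, p=fb)
                geno = np.sort(np.stack([a, b], axis=1), axis=1)
            elif g == "BC_A":
                a = rng.choice(sizes, size=s, p=fa)
                b = rng.choice(sizes, size=s, p=fmix)
                geno = np.sort(np.stack([a, b], axis=1), axis=1)
            else:  # BC_B
                a = rng.choice(sizes, size=s, p=fb)
                b = rng.choice(sizes, size=s, p=fmix)
                geno = np.sort(np.stack([a, b], axis=1), axis=1)
            calls[start:start + s, j, :] = geno
            start += s
    individuals = [f"{g}_{i}" for g in group_sizes for i in range(group_sizes[g])]
    gm = GenotypeMatrix(individuals, loci, calls, labels)
    truth = TruthRecord(
        "hybrid_panel",
        seed,
        dict(parent_fst=parent_fst, n_pure=n_pure, n_f1=n_f1, n_bc=n_bc,
             true_class={ind: lab for ind, lab in zip(individuals, labels)}),
    )
    return gm, truth


def _forward_drift(
    freq_list: list[np.ndarray] | None,
    sizes_list: list[np.ndarray],
    n_diploid: int,
    generations: int,
    rng: np.random.Generator,
    start_pop: np.ndarray | None = None,
) -> np.ndarray:
    """Forward Wright–Fisher of unlinked loci at genotype level (creates
    cross-locus LD by shared pedigree); returns final calls (n, L, 2).

    Starts either from HWE draws of ``freq_list`` or from an explicit
    genotype array (which preserves existing LD)."""
    if start_pop is not None:
        pop = start_pop.copy()
        n_diploid = pop.shape[0]
        L = pop.shape[1]
    else:
        L = len(freq_list)
        pop = np.zeros((n_diploid, L, 2), dtype=np.int64)
        for j in range(L):
            pop[:, j, :] = _hwe_genotypes(freq_list[j], sizes_list[j], n_diploid, rng)
    for _ in range(generations):
        mothers = rng.integers(0, n_diploid, size=n_diploid)
        fathers = rng.integers(0, n_diploid, size=n_diploid)
        pick_m = rng.integers(0, 2, size=(n_diploid, L))
        pick_f = rng.integers(0, 2, size=(n_diploid, L))
        child = np.empty_like(pop)
        rows = np.arange(n_diploid)[:, None]
        cols = np.arange(L)[None, :]
        child[:, :, 0] = pop[mothers[:, None], cols, pick_m]
        child[:, :, 1] = pop[fathers[:, None], cols, pick_f]
        pop = child
    return np.sort(pop, axis=2)


def make_domesticated_bottleneck(
    source_freqs: list[np.ndarray] | None = None,
    source_sizes: list[np.ndarray] | None = None,
    bottleneck_n: int = 15,
    generations: int = 60,
    n_strains: int = 4,
    strain_generations: int = 2,
    sample_n: int = 12,
    loci: Sequence[LocusDef] | None = None,
    n_alleles: int = 12,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Bottlenecked captive strains drifted forward from a wild source.

    A single founding lineage drifts for ``generations`` at size
    ``bottleneck_n``; each strain then continues independently for a few
    ``strain_generations`` (recent farm splits of one domesticated stock).
    This produces reduced allelic richness, inflated within-strain LD, and
    shallow between-strain differentiation relative to wild demes.
    ``generations = 0`` with ``strain_generations = 0`` leaves strains
    statistically identical to fresh source samples.
    """
    if bottleneck_n < 2:
        raise ValidationError("bottleneck_n must be >= 2")
    rng = spawn_rng(seed, "bottleneck")
    loci = list(loci) if loci is not None else default_loci()
    if source_freqs is None:
        source_sizes = [_allele_sizes(l, n_alleles, rng) for l in loci]
        source_freqs = [rng.dirichlet(np.ones(s.size)) for s in source_sizes]
    blocks = []
    labels = []
    # a reference sample from the source itself
    src_calls = np.zeros((sample_n, len(loci), 2), dtype=np.int64)
    for j in range(len(loci)):
        src_calls[:, j, :] = _hwe_genotypes(source_freqs[j], source_sizes[j], sample_n, rng)
    blocks.append(src_calls)
    labels += ["source"] * sample_n
    founder = _forward_drift(source_freqs, source_sizes, bottleneck_n, generations, rng)
    for s in range(n_strains):
        pop = _forward_drift(None, source_sizes, bottleneck_n,
                             strain_generations, rng, start_pop=founder)
        take = rng.choice(bottleneck_n, size=min(sample_n, bottleneck_n), replace=False)
        blocks.append(pop[take])
        labels += [f"strain_{s + 1}"] * len(take)
    calls = np.vstack(blocks)
    individuals = [f"ind_{i + 1}" for i in range(len(labels))]
    meta = {
        p: PopulationMetadata(p, provenance="wild" if p == "source" else "captive",
                              subcontinent="North America")
        for p in dict.fromkeys(labels)
    }
    gm = GenotypeMatrix(individuals, loci, calls, np.asarray(labels, dtype=object), meta)
    truth = TruthRecord(
        "domesticated_bottleneck",
        seed,
        dict(bottleneck_n=bottleneck_n, generations=generations, n_strains=n_strains),
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Study-scale world
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorldConfig:
    """Sampling frame mirroring the emulated study design."""

    n_populations: int = 150
    total_individuals: int = 2862
    n_loci: int = 15
    n_clusters: int = 16
    cluster_fst: float = 0.13
    pop_fst: float = 0.035
    dirichlet_alpha: float = 0.2
    captive_clusters: tuple[int, ...] = (0, 1, 2, 3)
    bottleneck_n: int = 50
    bottleneck_generations: int = 40
    pop_generations: int = 6  # extra per-population drift inside captive clusters
    fis: float = 0.12  # within-population inbreeding (heterozygote deficit)
    min_pop_size: int = 5
    max_pop_size: int = 50
    # populations per cluster (sums to n_populations)
    pops_per_cluster: tuple[int, ...] = (25, 15, 7, 3, 14, 15, 4, 4, 3, 5, 10, 8, 7, 8, 12, 10)


# rough geography for the 16 clusters: (subcontinent cycle, provenance);
# several clusters span subcontinents, which keeps the among-subcontinent
# variance share moderate as in globally traded/admixed sampling frames
_CLUSTER_GEO = (
    (("North America", "Europe", "Africa"), "captive"),
    (("Europe", "Africa"), "captive"),
    (("Europe",), "captive"),
    (("Asia",), "captive"),
    (("Asia",), "captive"),
    (("Asia",), "wild"),
    (("Australia",), "wild"),
    (("Australia",), "captive"),
    (("Australia",), "wild"),
    (("Europe",), "wild"),
    (("Africa",), "wild"),
    (("South America",), "wild"),
    (("Africa",), "wild"),
    (("South America",), "wild"),
    (("Central America",), "wild"),
    (("North America", "Central America", "Africa"), "wild"),
)


def make_global_fixture(
    config: SyntheticWorldConfig | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Study-scale world: 16 hierarchical clusters over ~150 populations.

    Wild clusters use two-level Dirichlet divergence (cluster then
    population) around skewed ancestral frequencies; captive clusters are
    forward-drifted bottleneck strains from a shared captive ancestor, which
    yields reduced richness and long-range LD.  Population sizes are drawn
    in [min, max] and adjusted to hit the configured total exactly.
    """
    cfg = config or SyntheticWorldConfig()
    if sum(cfg.pops_per_cluster) != cfg.n_populations:
        raise ValidationError("pops_per_cluster must sum to n_populations")
    rng = spawn_rng(seed, "global_fixture")
    loci = default_loci(cfg.n_loci)

    # population sizes: lognormal-ish around the study mean, exact total
    sizes = np.clip(
        np.round(rng.normal(cfg.total_individuals / cfg.n_populations, 7.5,
                            size=cfg.n_populations)),
        cfg.min_pop_size, cfg.max_pop_size,
    ).astype(int)
    while sizes.sum() != cfg.total_individuals:
        i = int(rng.integers(cfg.n_populations))
        if sizes.sum() < cfg.total_individuals and sizes[i] < cfg.max_pop_size:
            sizes[i] += 1
        elif sizes.sum() > cfg.total_individuals and sizes[i] > cfg.min_pop_size:
            sizes[i] -= 1

    n_alleles = [
        DEFAULT_ALLELE_COUNTS[j % len(DEFAULT_ALLELE_COUNTS)] for j in range(cfg.n_loci)
    ]
    allele_sizes = [_allele_sizes(l, n_alleles[j], rng) for j, l in enumerate(loci)]
    ancestral = [rng.dirichlet(np.full(s.size, cfg.dirichlet_alpha)) for s in allele_sizes]
    captive_root = [
        _deme_freqs(ancestral[j], cfg.cluster_fst, rng) for j in range(cfg.n_loci)
    ]

    cluster_freqs: list[list[np.ndarray] | None] = []
    cluster_pools: dict[int, np.ndarray] = {}
    for c in range(cfg.n_clusters):
        if c in cfg.captive_clusters:
            # a captive strain: bottleneck drift from the shared captive root;
            # the pool genotypes (not just frequencies) seed the farm samples
            # so the strain's long-range LD is inherited
            start = [_deme_freqs(captive_root[j], 0.05, rng) for j in range(cfg.n_loci)]
            cluster_pools[c] = _forward_drift(
                start, allele_sizes, cfg.bottleneck_n, cfg.bottleneck_generations, rng
            )
            cluster_freqs.append(None)
        else:
            cluster_freqs.append(
                [_deme_freqs(ancestral[j], cfg.cluster_fst, rng) for j in range(cfg.n_loci)]
            )

    calls_blocks = []
    pop_labels = []
    individuals = []
    metadata = {}
    truth_cluster = {}
    pop_id = 0
    for c, n_pops in enumerate(cfg.pops_per_cluster):
        sub_cycle, prov = _CLUSTER_GEO[c]
        for p_in_cluster in range(n_pops):
            sub = sub_cycle[p_in_cluster % len(sub_cycle)]
            pid = f"pop_{pop_id + 1:03d}"
            n = int(sizes[pop_id])
            pop_id += 1
            if c in cfg.captive_clusters:
                # farm sample of the shared strain: a few extra generations of
                # local drift keeps long-range LD without deep divergence
                pop = _forward_drift(
                    None, allele_sizes, cfg.bottleneck_n,
                    cfg.pop_generations, rng, start_pop=cluster_pools[c],
                )
                take = rng.choice(cfg.bottleneck_n, size=min(n, cfg.bottleneck_n),
                                  replace=False)
                block = pop[take]
                if len(block) < n:  # top up by resampling drifted frequencies
                    extra = np.zeros((n - len(block), cfg.n_loci, 2), dtype=np.int64)
                    for j in range(cfg.n_loci):
                        cnt = np.bincount(
                            np.searchsorted(allele_sizes[j], pop[:, j, :].ravel()),
                            minlength=allele_sizes[j].size,
                        ).astype(float)
                        extra[:, j, :] = _hwe_genotypes(
                            cnt / cnt.sum(), allele_sizes[j], n - len(block), rng
                        )
                    block = np.vstack([block, extra])
            else:
                pf = [
                    _deme_freqs(cluster_freqs[c][j], cfg.pop_fst, rng)
                    for j in range(cfg.n_loci)
                ]
                block = np.zeros((n, cfg.n_loci, 2), dtype=np.int64)
                for j in range(cfg.n_loci):
                    block[:, j, :] = _hwe_genotypes(
                        pf[j], allele_sizes[j], n, rng, fis=cfg.fis
                    )
            calls_blocks.append(block)
            pop_labels += [pid] * n
            individuals += [f"{pid}_i{i + 1}" for i in range(n)]
            lat = float(rng.uniform(-35, 55))
            lon = float(rng.uniform(-120, 150))
            metadata[pid] = PopulationMetadata(
                pid, provenance=prov, subcontinent=sub, lat=lat, lon=lon
            )
            truth_cluster[pid] = c
    calls = np.vstack(calls_blocks)
    gm = GenotypeMatrix(
        individuals, loci, calls, np.asarray(pop_labels, dtype=object), metadata
    )
    truth = TruthRecord(
        "global_fixture",
        seed,
        dict(
            n_clusters=cfg.n_clusters,
            cluster_fst=cfg.cluster_fst,
            pop_fst=cfg.pop_fst,
            cluster_of_population=truth_cluster,
            population_sizes={p: int(s) for p, s in zip(metadata, sizes)},
        ),
    )
    return gm, truth
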