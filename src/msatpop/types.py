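"""Core data structures shared by all analysis stages.

Alleles are stored as integer fragment sizes in base pairs (as scored
against an internal size standard), never as repeat counts.  Genotypes are
unphased diploid calls; the pair order within a call is non-semantic and is
canonicalised to ascending order.  Missing calls use ``MISSING`` (-1)
internally regardless of the per-locus sentinel used on disk.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: internal sentinel for a missing allele copy
MISSING: int = -1

SUBCONTINENTS = (
    "South America",
    "Central America",
    "North America",
    "Africa",
    "Asia",
    "Australia",
    "Europe",
)

PROVENANCES = ("wild", "captive")


class ValidationError(ValueError):
    """Raised when an input violates a declared invariant."""


class ParseError(ValueError):
    """Raised when a genotype table cannot be parsed."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name:
        Locus identifier.
    motif_length:
        Repeat motif length in bp (2 for dinucleotide, 3 for trinucleotide).
    size_range:
        Inclusive ``(min, max)`` allele size bounds in bp.
    missing_code:
        Integer sentinel used in input tables for a missing allele; must lie
        outside ``size_range``.
    """

    name: str
    motif_length: int = 2
    size_range: tuple[int, int] = (80, 500)
    missing_code: int = 0

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValidationError(f"locus {self.name}: motif_length must be >= 1")
        lo, hi = self.size_range
        if not lo < hi:
            raise ValidationError(f"locus {self.name}: size_range min must be < max")
        if lo <= self.missing_code <= hi:
            raise ValidationError(
                f"locus {self.name}: missing_code {self.missing_code} lies inside size_range"
            )

    def contains(self, size: int) -> bool:
        lo, hi = self.size_range
        return lo <= size <= hi


@dataclass(frozen=True)
class PopulationMetadata:
    """Per-population sampling metadata."""

    population_id: str
    provenance: str = "wild"
    subcontinent: str = "South America"
    country: str | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"population {self.population_id}: provenance {self.provenance!r} "
                f"not in {PROVENANCES}"
            )
        if self.subcontinent not in SUBCONTINENTS:
            raise ValidationError(
                f"population {self.population_id}: subcontinent {self.subcontinent!r} "
                f"not in {SUBCONTINENTS}"
            )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"population {self.population_id}: lat out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"population {self.population_id}: lon out of range")


class GenotypeMatrix:
    """Diploid microsatellite calls for a set of individuals.

    Attributes
    ----------
    individuals:
        Ordered individual identifiers, length ``n``.
    loci:
        Ordered :class:`LocusDef` list, length ``L``.
    calls:
        ``(n, L, 2)`` int array of allele sizes in bp, ``MISSING`` where no
        call was made; the two copies of each call are sorted ascending
        (missing sorts last).
    populations:
        Length-``n`` array of population ids.
    metadata:
        Mapping population id -> :class:`PopulationMetadata`.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[LocusDef],
        calls: np.ndarray,
        populations: Sequence[str],
        metadata: Mapping[str, PopulationMetadata] | None = None,
        validate: bool = True,
    ) -> None:
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        self.calls = _canonicalise(calls)
        self.populations = np.asarray(populations, dtype=object)
        if self.populations.shape[0] != len(self.individuals):
            raise ValidationError("populations length does not match individuals")
        if metadata is None:
            metadata = {
                p: PopulationMetadata(population_id=p) for p in self.population_ids
            }
        self.metadata = dict(metadata)
        self._locus_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if validate:
            self._validate()

    # -- basic shape ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    def _validate(self) -> None:
        for j, locus in enumerate(self.loci):
            col = self.calls[:, j, :]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            bad = obs[(obs < locus.size_range[0]) | (obs > locus.size_range[1])]
            if bad.size:
                raise ValidationError(
                    f"locus {locus.name}: allele size {int(bad[0])} outside "
                    f"declared range {locus.size_range}"
                )
        # exactly one half-missing copy per call is disallowed: calls are pairs
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValidationError(
                f"individual {self.individuals[i]} locus {self.loci[j].name}: "
                "single-allele call (calls must be full pairs or fully missing)"
            )
        missing_meta = set(self.population_ids) - set(self.metadata)
        if missing_meta:
            raise ValidationError(f"populations without metadata: {sorted(missing_meta)}")

    # -- views ---------------------------------------------------------

    @property
    def missing_mask(self) -> np.ndarray:
        """``(n, L)`` boolean mask, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def population_indices(self) -> dict[str, np.ndarray]:
        """Mapping population id -> integer row indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            out.setdefault(p, []).append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}

    def locus_codes(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(codes, sizes)`` for locus ``j``.

        ``codes`` is ``(n, 2)`` with allele indices into ``sizes`` and -1 for
        missing; ``sizes`` is the sorted array of distinct observed allele
        sizes at the locus.
        """
        if j not in self._locus_cache:
            col = self.calls[:, j, :]
            obs = col[col != MISSING]
            sizes = np.unique(obs)
            codes = np.full(col.shape, -1, dtype=np.int64)
            if sizes.size:
                present = col != MISSING
                codes[present] = np.searchsorted(sizes, col[present])
            self._locus_cache[j] = (codes, sizes)
        return self._locus_cache[j]

    def subset(self, rows: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=np.intp)
        return GenotypeMatrix(
            [self.individuals[i] for i in rows],
            self.loci,
            self.calls[rows],
            self.populations[rows],
            self.metadata,
            validate=False,
        )

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.population_ids:
            m = self.metadata[pid]
            rows.append(
                dict(
                    population=m.population_id,
                    provenance=m.provenance,
                    subcontinent=m.subcontinent,
                    country=m.country,
                    lat=m.lat,
                    lon=m.lon,
                )
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {self.n_populations} populations)"
        )


def _canonicalise(calls: np.ndarray) -> np.ndarray:
    """Sort each allele pair ascending with missing copies last."""
    c = calls.copy()
    # map MISSING to +inf-like for sorting, then back
    big = np.iinfo(np.int64).max
    tmp = np.where(c == MISSING, big, c)
    tmp.sort(axis=2)
    return np.where(tmp == big, MISSING, tmp)


@dataclass
class DatasetSummary:
    """Headline counts for a genotype matrix."""

    n_individuals: int
    n_populations: int
    n_loci: int
    unique_mlg_count: int
    missing_rate: float
    population_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def mean_population_size(self) -> float:
        return float(np.mean(list(self.population_sizes.values())))

    @property
    def min_population_size(self) -> int:
        return int(min(self.population_sizes.values()))

    @property
    def max_population_size(self) -> int:
        return int(max(self.population_sizes.values()))

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_populations": self.n_populations,
            "n_loci": self.n_loci,
            "unique_mlg_count": self.unique_mlg_count,
            "missing_rate": self.missing_rate,
            "population_sizes": dict(self.population_sizes),
            "mean_population_size": self.mean_population_size,
            "min_population_size": self.min_population_size,
            "max_population_size": self.max_population_size,
        }


def spawn_rng(seed: int | np.random.Generator | None, *path: str) -> np.random.Generator:
    """Deterministically derive a generator for a named sub-stage.

    A master integer seed plus a path of stage names maps to an independent
    stream, so stages can be rerun in isolation with identical results.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if path:
        digest = [zlib.crc32(p.encode("utf-8")) for p in path]
        ss = np.random.SeedSequence([seed if seed is not None else 0, *digest])
    else:
        ss = np.random.SeedSequence(seed)
    return np.random.default_rng(ss)
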