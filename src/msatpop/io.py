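"""Reading, validating and exporting diploid microsatellite genotype tables.

Two on-disk layouts are supported for the genotype columns:

* two columns per locus, named ``<locus>_1`` / ``<locus>_2``;
* one column per locus named ``<locus>`` holding ``size1/size2``.

A header row is mandatory and the population column is ``population`` by
default.  Optional metadata columns (``provenance``, ``subcontinent``,
``country``, ``lat``, ``lon``) must be constant within a population.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DatasetSummary,
    GenotypeMatrix,
    LocusDef,
    ParseError,
    PopulationMetadata,
    ValidationError,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "write_genepop",
    "read_genepop",
    "dataset_summary",
]

_META_COLS = ("provenance", "subcontinent", "country", "lat", "lon")


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:8192]
    if not sample.strip():
        raise ParseError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_genotype_table(
    path: str | Path,
    locus_defs: Sequence[LocusDef],
    delimiter: str | None = None,
    population_column: str = "population",
) -> GenotypeMatrix:
    """Parse a delimited genotype table into a validated matrix.

    Missing codes declared per locus are mapped onto the internal missing
    mask; allele pairs are canonicalised to ascending order.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no data rows")
    cols = set(df.columns)
    if population_column not in cols:
        raise ParseError(f"{path}: missing population column {population_column!r}")

    n = df.shape[0]
    calls = np.full((n, len(locus_defs), 2), MISSING, dtype=np.int64)
    for j, locus in enumerate(locus_defs):
        if f"{locus.name}_1" in cols and f"{locus.name}_2" in cols:
            raw = np.stack(
                [
                    _parse_int_col(df[f"{locus.name}_1"], locus, path),
                    _parse_int_col(df[f"{locus.name}_2"], locus, path),
                ],
                axis=1,
            )
        elif locus.name in cols:
            raw = _parse_pair_col(df[locus.name], locus, path)
        else:
            raise ParseError(f"{path}: no columns found for locus {locus.name}")
        raw[raw == locus.missing_code] = MISSING
        calls[:, j, :] = raw

    individuals = (
        df["individual"].tolist()
        if "individual" in cols
        else [f"ind_{i}" for i in range(n)]
    )
    populations = df[population_column].tolist()
    metadata = _metadata_from_frame(df, population_column)
    return GenotypeMatrix(individuals, locus_defs, calls, populations, metadata)


def _parse_int_col(col: pd.Series, locus: LocusDef, path: Path) -> np.ndarray:
    out = np.empty(len(col), dtype=np.int64)
    for i, v in enumerate(col):
        v = v.strip()
        if v in ("", "NA"):
            out[i] = locus.missing_code
            continue
        try:
            out[i] = int(v)
        except ValueError:
            raise ParseError(
                f"{path}: row {i + 2}: cannot parse allele {v!r} at locus {locus.name}"
            ) from None
    return out


def _parse_pair_col(col: pd.Series, locus: LocusDef, path: Path) -> np.ndarray:
    out = np.empty((len(col), 2), dtype=np.int64)
    for i, v in enumerate(col):
        v = v.strip()
        if v in ("", "NA"):
            out[i] = locus.missing_code
            continue
        parts = v.split("/")
        if len(parts) != 2:
            raise ParseError(
                f"{path}: row {i + 2}: malformed call {v!r} at locus {locus.name}"
            )
        try:
            out[i, 0] = int(parts[0])
            out[i, 1] = int(parts[1])
        except ValueError:
            raise ParseError(
                f"{path}: row {i + 2}: cannot parse call {v!r} at locus {locus.name}"
            ) from None
    return out


def _metadata_from_frame(df: pd.DataFrame, population_column: str) -> dict:
    meta: dict[str, PopulationMetadata] = {}
    have = [c for c in _META_COLS if c in df.columns]
    for pid, sub in df.groupby(population_column, sort=False):
        kw: dict = {"population_id": pid}
        for c in have:
            vals = set(sub[c])
            if len(vals) > 1:
                raise ValidationError(
                    f"population {pid}: metadata column {c!r} is not constant"
                )
            v = next(iter(vals)).strip()
            if v in ("", "NA"):
                continue
            kw[c] = float(v) if c in ("lat", "lon") else v
        meta[pid] = PopulationMetadata(**kw)
    return meta


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, delimiter: str = ",") -> Path:
    """Write the two-columns-per-locus dialect (round-trips with the reader)."""
    path = Path(path)
    rows = {}
    rows["individual"] = gm.individuals
    rows["population"] = list(gm.populations)
    meta = {p: gm.metadata[p] for p in gm.population_ids}
    for c in _META_COLS:
        vals = [getattr(meta[p], c if c != "provenance" else "provenance") for p in gm.populations]
        if any(v is not None for v in vals):
            rows[c] = ["" if v is None else v for v in vals]
    for j, locus in enumerate(gm.loci):
        col = gm.calls[:, j, :]
        enc = np.where(col == MISSING, locus.missing_code, col)
        rows[f"{locus.name}_1"] = enc[:, 0]
        rows[f"{locus.name}_2"] = enc[:, 1]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    return path


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str | None = None) -> Path:
    """Export in GenePop 4.x text format with 3-digit allele codes.

    Allele sizes are encoded directly when < 1000, otherwise as offsets from
    ``size_range[0] - 1`` so codes stay within three digits (code 000 is the
    missing convention).  Raises when a locus cannot be encoded.
    """
    path = Path(path)
    offsets = []
    for locus in gm.loci:
        col = gm.calls[:, :, :][:, gm.loci.index(locus), :]
        obs = col[col != MISSING]
        hi = int(obs.max()) if obs.size else locus.size_range[1]
        lo = int(obs.min()) if obs.size else locus.size_range[0]
        if hi <= 999:
            offsets.append(0)
        else:
            off = lo - 1
            if hi - off > 999:
                raise ValidationError(
                    f"locus {locus.name}: allele span {lo}-{hi} not encodable "
                    "as 3-digit GenePop codes"
                )
            offsets.append(off)

    lines = [title or "msatpop GenePop export"]
    lines.extend(l.name for l in gm.loci)
    pop_index = gm.population_indices()
    for pid, rows in pop_index.items():
        lines.append("Pop")
        for i in rows:
            codes = []
            for j in range(gm.n_loci):
                a, b = gm.calls[i, j]
                if a == MISSING:
                    codes.append("000000")
                else:
                    codes.append(f"{a - offsets[j]:03d}{b - offsets[j]:03d}")
            lines.append(f"{gm.individuals[i]} ,  " + " ".join(codes))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    # stash offsets so a paired reader can restore absolute sizes
    Path(str(path) + ".offsets.json").write_text(
        json.dumps({l.name: o for l, o in zip(gm.loci, offsets)}), encoding="utf-8"
    )
    return path


def read_genepop(path: str | Path, locus_defs: Sequence[LocusDef] | None = None) -> GenotypeMatrix:
    """Read a GenePop file written by :func:`write_genepop` (or compatible)."""
    path = Path(path)
    lines = [l.rstrip("\n") for l in path.read_text(encoding="utf-8").splitlines()]
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # loci may be one per line or comma separated
        locus_names.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    offsets_path = Path(str(path) + ".offsets.json")
    offsets = (
        json.loads(offsets_path.read_text(encoding="utf-8"))
        if offsets_path.exists()
        else {n: 0 for n in locus_names}
    )
    if locus_defs is None:
        locus_defs = [LocusDef(name=n, size_range=(1, 10**6), missing_code=0) for n in locus_names]

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_counter += 1
            i += 1
            continue
        line = body[i]
        i += 1
        if not line.strip():
            continue
        name, _, genos = line.partition(",")
        codes = genos.split()
        if len(codes) != len(locus_names):
            raise ParseError(f"{path}: bad genotype count on line {i + 1}")
        row = []
        for ln, c in zip(locus_names, codes):
            if len(c) not in (4, 6):
                raise ParseError(f"{path}: bad allele code {c!r}")
            half = len(c) // 2
            a, b = int(c[:half]), int(c[half:])
            off = offsets.get(ln, 0)
            row.append(
                (MISSING, MISSING) if a == 0 or b == 0 else (a + off, b + off)
            )
        individuals.append(name.strip())
        populations.append(f"pop_{pop_counter}")
        rows.append(row)
    calls = np.asarray(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, list(locus_defs), calls, populations)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


def dataset_summary(gm: GenotypeMatrix) -> DatasetSummary:
    """Headline counts, including distinct multilocus genotypes.

    Missing calls are treated as a distinct value when comparing genotypes,
    so two individuals differing only in missingness are distinct MLGs.
    """
    if gm.n_individuals == 0:
        raise ValidationError("empty matrix")
    flat = gm.calls.reshape(gm.n_individuals, -1)
    unique = np.unique(flat, axis=0).shape[0]
    sizes = {p: int(len(ix)) for p, ix in gm.population_indices().items()}
    return DatasetSummary(
        n_individuals=gm.n_individuals,
        n_populations=gm.n_populations,
        n_loci=gm.n_loci,
        unique_mlg_count=int(unique),
        missing_rate=float(gm.missing_mask.mean()),
        population_sizes=sizes,
    )
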