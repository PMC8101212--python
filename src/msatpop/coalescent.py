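"""Multi-population coalescent simulation of microsatellites under a
generalised stepwise mutation model (GSM) with single-nucleotide indels.

The engine is a continuous-time backward coalescent: within each population
of diploid size N, k lineages coalesce at rate k(k-1)/(4N) per generation;
demographic events (population merges, admixture splits, size changes) are
processed at their scheduled times moving backward.  Mutations are laid on
branches as a Poisson process; step magnitudes are geometric with parameter
P (the strict stepwise model is the P -> 0 limit), reflected at the bounds
of a contiguous allele-state range.  Rare single-nucleotide indels toggle a
+-1 bp offset so alleles with equal repeat counts can differ in size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import GenotypeMatrix, LocusDef, PopulationMetadata, ValidationError, spawn_rng

__all__ = [
    "Uniform",
    "DemographicEvent",
    "Scenario",
    "MutationModel",
    "ParamDraw",
    "Genealogy",
    "sample_priors",
    "simulate_genealogy",
    "mutate_gsm",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Uniform:
    """Uniform prior over [lo, hi]; degenerate when lo == hi."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValidationError("prior bounds must be finite")
        if self.hi < self.lo:
            raise ValidationError("prior upper bound below lower bound")

    def draw(self, rng: np.random.Generator) -> float:
        if self.hi == self.lo:
            return self.lo
        return float(rng.uniform(self.lo, self.hi))


ParamLike = float | int | Uniform


def _resolve(v: ParamLike, rng: np.random.Generator) -> float:
    return v.draw(rng) if isinstance(v, Uniform) else float(v)


@dataclass(frozen=True)
class DemographicEvent:
    """One timed event, moving backward from the present.

    kinds:
      * ``merge``: lineages in ``source`` move to ``sink``
      * ``admix``: lineages in ``pop`` move to ``source_a`` with probability
        ``rate`` else to ``source_b``
      * ``size_change``: population ``pop`` takes diploid size ``size``
    """

    time: ParamLike
    kind: str
    pop: str | None = None
    source: str | None = None
    sink: str | None = None
    source_a: str | None = None
    source_b: str | None = None
    rate: ParamLike | None = None
    size: ParamLike | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("merge", "admix", "size_change"):
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass
class Scenario:
    """A demographic model: populations, sample sizes and an event program."""

    name: str
    populations: Mapping[str, ParamLike]
    samples: Mapping[str, int]
    events: Sequence[DemographicEvent] = field(default_factory=tuple)

    def validate(self) -> None:
        for p in self.samples:
            if p not in self.populations:
                raise ValidationError(f"sampled population {p!r} not declared")
        for e in self.events:
            for ref in (e.pop, e.source, e.sink, e.source_a, e.source_b):
                if ref is not None and ref not in self.populations:
                    raise ValidationError(f"event references unknown population {ref!r}")


@dataclass(frozen=True)
class MutationModel:
    """GSM mutation priors (means are per locus per generation)."""

    mu_mean: ParamLike = Uniform(1e-5, 1e-3)
    p_geom: ParamLike = Uniform(0.1, 0.99)
    mu_sni: ParamLike = Uniform(1e-8, 1e-5)
    rate_shape: float = 2.0  # Gamma shape of per-locus rate heterogeneity
    shared_rate: bool = False
    n_states: int = 40


@dataclass
class ParamDraw:
    scenario: str
    values: dict[str, float]
    locus_rates: np.ndarray
    seed: int | None


def sample_priors(
    scenario: Scenario,
    model: MutationModel,
    n_loci: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ParamDraw:
    """Draw every free parameter of a scenario + mutation model.

    Per-locus mutation rates are Gamma(shape, mean = mu_mean) unless the
    model declares a shared rate.
    """
    if rng is None:
        rng = spawn_rng(seed, "priors", scenario.name)
    values: dict[str, float] = {}
    for name, size in scenario.populations.items():
        values[f"N_{name}"] = _resolve(size, rng)
    for i, e in enumerate(scenario.events):
        values[f"t_{i}"] = _resolve(e.time, rng)
        if e.kind == "admix":
            r = _resolve(e.rate, rng)
            if not 0.0 <= r <= 1.0:
                raise ValidationError("admixture rate outside [0, 1]")
            values[f"r_{i}"] = r
        if e.kind == "size_change":
            values[f"size_{i}"] = _resolve(e.size, rng)
    values["mu_mean"] = _resolve(model.mu_mean, rng)
    values["P"] = _resolve(model.p_geom, rng)
    values["mu_sni"] = _resolve(model.mu_sni, rng)
    if model.shared_rate:
        rates = np.full(n_loci, values["mu_mean"])
    else:
        rates = rng.gamma(model.rate_shape, values["mu_mean"] / model.rate_shape, size=n_loci)
    return ParamDraw(scenario.name, values, rates, seed)


def _param_from_json(v: object) -> ParamLike:
    if isinstance(v, (list, tuple)):
        if len(v) != 2:
            raise ValidationError(f"prior must be [lo, hi], got {v!r}")
        return Uniform(float(v[0]), float(v[1]))
    return float(v)


def scenario_from_dict(d: Mapping) -> Scenario:
    """Build a scenario from the declarative key-value format.

    Numeric values may be scalars (fixed) or two-element ``[lo, hi]`` lists
    (uniform priors)::

        {"name": "m1",
         "populations": {"a": [500, 5000], "b": 1000},
         "samples": {"a": 12, "b": 12},
         "events": [{"time": [10, 200], "kind": "merge",
                     "source": "b", "sink": "a"}]}
    """
    events = []
    for e in d.get("events", []):
        kw = dict(e)
        kw["time"] = _param_from_json(kw["time"])
        if "rate" in kw and kw["rate"] is not None:
            kw["rate"] = _param_from_json(kw["rate"])
        if "size" in kw and kw["size"] is not None:
            kw["size"] = _param_from_json(kw["size"])
        events.append(DemographicEvent(**kw))
    sc = Scenario(
        name=d["name"],
        populations={k: _param_from_json(v) for k, v in d["populations"].items()},
        samples={k: int(v) for k, v in d["samples"].items()},
        events=tuple(events),
    )
    sc.validate()
    return sc


def mutation_model_from_dict(d: Mapping) -> MutationModel:
    kw = {}
    for src, dst in (("mu_mean", "mu_mean"), ("P", "p_geom"), ("mu_sni", "mu_sni")):
        if src in d:
            kw[dst] = _param_from_json(d[src])
    for opt in ("rate_shape", "shared_rate", "n_states"):
        if opt in d:
            kw[opt] = d[opt]
    return MutationModel(**kw)


def load_scenario_file(path) -> tuple[list[Scenario], MutationModel]:
    """Read a JSON scenario file: {"mutation": {...}, "scenarios": [...]}."""
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text(encoding="utf-8"))
    scens = [scenario_from_dict(s) for s in data["scenarios"]]
    model = mutation_model_from_dict(data.get("mutation", {}))
    return scens, model


@dataclass
class Genealogy:
    """Binary timed genealogy over sampled gene copies.

    Nodes 0..n_leaves-1 are leaves (time 0 unless sampled otherwise);
    ``parent[i]`` is -1 for the root.  ``leaf_pop`` gives the sampled
    population of each leaf.
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_pop: list[str]

    @property
    def tmrca(self) -> float:
        return float(self.time.max())


def simulate_genealogy(
    scenario: Scenario,
    draw: ParamDraw,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one locus genealogy under the scenario with drawn parameters."""
    if rng is None:
        rng = spawn_rng(seed, "genealogy", scenario.name)
    scenario.validate()
    sizes = {p: draw.values[f"N_{p}"] for p in scenario.populations}
    for p, n in sizes.items():
        if n <= 0:
            raise ValidationError(f"population {p!r} has non-positive size")

    lineages: dict[str, list[int]] = {p: [] for p in scenario.populations}
    leaf_pop: list[str] = []
    node = 0
    for p, k in scenario.samples.items():
        for _ in range(2 * k):
            lineages[p].append(node)
            leaf_pop.append(p)
            node += 1
    n_leaves = node
    parent = list(range(n_leaves))
    times = [0.0] * n_leaves
    # pre-extend as needed
    events = sorted(enumerate(scenario.events), key=lambda ie: draw.values[f"t_{ie[0]}"])
    ev_ptr = 0
    t = 0.0
    active = {p for p in scenario.populations}
    n_live = n_leaves

    while True:
        rates = {
            p: len(lineages[p]) * (len(lineages[p]) - 1) / (4.0 * sizes[p])
            for p in active
            if len(lineages[p]) >= 2
        }
        total = sum(rates.values())
        next_ev_t = (
            draw.values[f"t_{events[ev_ptr][0]}"] if ev_ptr < len(events) else math.inf
        )
        if total > 0:
            dt = rng.exponential(1.0 / total)
        else:
            dt = math.inf
        if t + dt >= next_ev_t:
            if math.isinf(next_ev_t):
                if n_live > 1:
                    raise ValidationError(
                        f"scenario {scenario.name!r}: lineages stranded in "
                        f"{[p for p in active if lineages[p]]} with no further events"
                    )
                break
            t = next_ev_t
            i, e = events[ev_ptr]
            ev_ptr += 1
            if e.kind == "merge":
                lineages[e.sink].extend(lineages[e.source])
                lineages[e.source] = []
                active.discard(e.source)
            elif e.kind == "admix":
                movers = lineages[e.pop]
                lineages[e.pop] = []
                active.discard(e.pop)
                r = draw.values[f"r_{i}"]
                for ln in movers:
                    (lineages[e.source_a] if rng.random() < r else lineages[e.source_b]).append(ln)
            elif e.kind == "size_change":
                sizes[e.pop] = draw.values[f"size_{i}"]
            continue
        t += dt
        # choose population proportional to rate
        u = rng.random() * total
        acc = 0.0
        for p, rr in rates.items():
            acc += rr
            if u <= acc:
                break
        pool = lineages[p]
        m = len(pool)
        i1 = int(rng.integers(m))
        i2 = int(rng.integers(m - 1))
        if i2 >= i1:
            i2 += 1
        a, b = pool[i1], pool[i2]
        new = len(parent)
        parent.append(new)
        times.append(t)
        parent[a] = new
        parent[b] = new
        # remove the two, add the parent
        if i1 < i2:
            i1, i2 = i2, i1
        pool.pop(i1)
        pool.pop(i2)
        pool.append(new)
        n_live -= 1
        if n_live == 1 and ev_ptr >= len(events):
            break

    parent_arr = np.asarray(parent, dtype=np.int64)
    root = len(parent_arr) - 1
    parent_arr[root] = -1
    return Genealogy(parent_arr, np.asarray(times), n_leaves, leaf_pop)


def mutate_gsm(
    genealogy: Genealogy,
    rate: float,
    p_geom: float,
    mu_sni: float,
    motif_length: int,
    n_states: int = 40,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Drop GSM + SNI mutations on the genealogy; return leaf allele sizes
    in bp relative to a zero baseline (repeat-state * motif + offset).

    Step magnitudes k >= 1 have P(k) = (1-P) P^(k-1) with equiprobable sign;
    states reflect at the range bounds.  SNI events toggle the bp offset by
    +-1, capped at +-2.
    """
    if rng is None:
        rng = spawn_rng(seed, "gsm")
    n_nodes = len(genealogy.parent)
    order = np.argsort(genealogy.time, kind="stable")[::-1]  # root first
    state = np.empty(n_nodes, dtype=np.int64)
    offset = np.zeros(n_nodes, dtype=np.int64)
    root = order[0]
    state[root] = n_states // 2
    hi = n_states - 1
    nonroot = order[1:]
    blens = genealogy.time[genealogy.parent[nonroot]] - genealogy.time[nonroot]
    n_mut = rng.poisson(rate * blens)
    n_sni = rng.poisson(mu_sni * blens)
    total_mut = int(n_mut.sum())
    steps = rng.geometric(1.0 - p_geom, size=total_mut) if total_mut else np.empty(0, int)
    signs = rng.random(total_mut) < 0.5
    sni_signs = rng.random(int(n_sni.sum())) < 0.5
    mi = si = 0
    for idx, v in enumerate(nonroot):
        u = genealogy.parent[v]
        s = state[u]
        for _ in range(n_mut[idx]):
            k = int(steps[mi])
            s += k if signs[mi] else -k
            mi += 1
            while s < 0 or s > hi:  # reflecting bounds
                if s < 0:
                    s = -s
                if s > hi:
                    s = 2 * hi - s
        state[v] = s
        off = offset[u]
        for _ in range(n_sni[idx]):
            off += 1 if sni_signs[si] else -1
            si += 1
            off = max(-2, min(2, off))
        offset[v] = off
    leaves = slice(0, genealogy.n_leaves)
    return state[leaves] * motif_length + offset[leaves]


def simulate_dataset(
    scenario: Scenario,
    model: MutationModel,
    loci: Sequence[LocusDef],
    seed: int | None = None,
    draw: ParamDraw | None = None,
    rng: np.random.Generator | None = None,
    metadata: Mapping[str, PopulationMetadata] | None = None,
) -> tuple[GenotypeMatrix, ParamDraw]:
    """Full pipeline: draw priors, simulate each locus, emit a genotype
    matrix with allele sizes mapped into each locus's declared range."""
    if rng is None:
        rng = spawn_rng(seed, "dataset", scenario.name)
    if draw is None:
        draw = sample_priors(scenario, model, len(loci), rng=rng)
    pops = [p for p, k in scenario.samples.items() if k > 0]
    n_ind = sum(scenario.samples[p] for p in pops)
    calls = np.zeros((n_ind, len(loci), 2), dtype=np.int64)
    individuals: list[str] = []
    populations: list[str] = []
    for p in pops:
        for i in range(scenario.samples[p]):
            individuals.append(f"{p}_{i}")
            populations.append(p)
    for j, locus in enumerate(loci):
        n_states = _states_for(locus, model.n_states)
        gen = simulate_genealogy(scenario, draw, rng=rng)
        sizes_rel = mutate_gsm(
            gen,
            rate=float(draw.locus_rates[j]),
            p_geom=draw.values["P"],
            mu_sni=draw.values["mu_sni"],
            motif_length=locus.motif_length,
            n_states=n_states,
            rng=rng,
        )
        base = locus.size_range[0] + 2
        sizes_abs = base + sizes_rel
        # leaves were emitted population-block by population-block, two per ind
        ptr = 0
        for i in range(n_ind):
            calls[i, j, 0] = sizes_abs[ptr]
            calls[i, j, 1] = sizes_abs[ptr + 1]
            ptr += 2
    gm = GenotypeMatrix(
        individuals, list(loci), calls, populations, metadata, validate=False
    )
    return gm, draw


def _states_for(locus: LocusDef, default_states: int) -> int:
    lo, hi = locus.size_range
    fit = (hi - lo - 4) // locus.motif_length + 1
    return max(2, min(default_states, int(fit)))
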