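"""Genetic-algorithm knockout search over binary reaction-inclusion genotypes.

A strain is a binary chromosome over the *deletable* reactions of a parent
model (1 = reaction present, 0 = knocked out); reactions whose single removal
drives the maximal product or biomass yield to zero are protected and always
present.  Strain fitness is computed without re-enumeration via the
knockout-subset property: a parent elementary mode survives iff its support
avoids the removed reactions.  The surviving modes are weighted (equally or
thermodynamically), the flux vector is reconstructed, and yields are
expressed as fractions of the *parent* model's theoretical yields:

* ``product``  — product mass yield / theoretical product yield,
* ``biomass``  — biomass-per-substrate / theoretical biomass yield,
* ``coupled``  — the product of the two fractions, which rewards strains
  that grow and produce simultaneously.

All three fitness values lie in [0, 1]; degenerate strains (no surviving
modes, or zero total thermodynamic weight) score 0 rather than raising.
An exhaustive search over bounded knockout counts provides the optimization
oracle used by the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np

from .efm import EMSet, enumerate_efms, max_yield
from .model_io import StoichiometricModel, apply_knockouts
from .thermo import (
    T_DEFAULT,
    ThermoTable,
    WeightVector,
    equal_weights,
    thermo_weights,
    weighted_yields,
)

_EXHAUSTIVE_BUDGET = 10**6

FITNESS_KINDS = ("product", "biomass", "coupled")
WEIGHTING_SCHEMES = ("equal", "thermodynamic")
SELECTION_METHODS = ("tournament", "roulette")


@dataclass
class GAConfig:
    """Search settings; the defaults mirror a small-population elitist GA
    with two-point crossover, uniform per-bit mutation and tournament
    selection, seeded with 2–6 knockouts per individual."""

    population_size: int = 50
    elite_count: int = 5
    initial_knockouts_range: tuple[int, int] = (2, 6)
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.01
    selection: str = "tournament"
    tournament_size: int = 2
    stall_tolerance: float = 1e-6
    stall_generations: int = 25
    max_generations: int = 100
    rng_seed: int = 0
    weighting_scheme: str = "equal"
    fitness: str = "coupled"
    temperature: float = T_DEFAULT

    def validate(self) -> None:
        if not (0 < self.elite_count < self.population_size):
            raise ValueError("elite_count must be in (0, population_size)")
        for name in ("crossover_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.initial_knockouts_range
        if lo < 0 or hi < lo:
            raise ValueError("initial_knockouts_range must satisfy 0 <= lo <= hi")
        if self.fitness not in FITNESS_KINDS:
            raise ValueError(f"fitness must be one of {FITNESS_KINDS}")
        if self.weighting_scheme not in WEIGHTING_SCHEMES:
            raise ValueError(f"weighting_scheme must be one of {WEIGHTING_SCHEMES}")
        if self.selection not in SELECTION_METHODS:
            raise ValueError(f"selection must be one of {SELECTION_METHODS}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass(frozen=True)
class FitnessRecord:
    product_fraction: float
    biomass_fraction: float
    n_modes: int
    n_removals: int

    @property
    def coupled(self) -> float:
        return self.product_fraction * self.biomass_fraction

    def fitness(self, kind: str) -> float:
        if kind == "product":
            return self.product_fraction
        if kind == "biomass":
            return self.biomass_fraction
        if kind == "coupled":
            return self.coupled
        raise ValueError(f"unknown fitness kind {kind!r}")


@dataclass(frozen=True)
class Chromosome:
    """Binary inclusion vector over deletable reactions, with its fitness."""

    bits: tuple[int, ...]
    fitness: float = 0.0
    record: FitnessRecord | None = None

    @property
    def n_removals(self) -> int:
        return len(self.bits) - sum(self.bits)


# ---------------------------------------------------------------------------
# Essentiality pre-screen
# ---------------------------------------------------------------------------


def essential_reactions(
    model: StoichiometricModel, ems: EMSet | None = None
) -> set[str]:
    """Reactions whose single removal kills all product or all biomass.

    Single-removal analysis on the wild-type model: remove each reaction,
    keep the parent modes avoiding it (knockout-subset property), and
    protect the reaction iff the surviving maximal product yield or maximal
    biomass yield is zero.  The returned set is fixed to 1 in every
    chromosome.
    """
    if ems is None:
        ems = enumerate_efms(model)
    protected: set[str] = set()
    for rid in model.reaction_ids:
        surviving = ems.filter_knockouts([rid])
        p = max_yield(surviving, model, "product")["value"]
        b = max_yield(surviving, model, "biomass")["value"]
        if p <= 0.0 or b <= 0.0:
            protected.add(rid)
    return protected


# ---------------------------------------------------------------------------
# Strain evaluation
# ---------------------------------------------------------------------------


class StrainEvaluator:
    """Evaluates knockout genotypes against a fixed parent model.

    Enumerates the parent EM set and theoretical yields once; strain
    evaluations filter the parent modes and are cached by chromosome.
    ``reenumerate=True`` switches to per-strain re-enumeration of the
    knockout submodel (slow debug path; result is identical by the
    knockout-subset property).
    """

    def __init__(
        self,
        model: StoichiometricModel,
        cfg: GAConfig,
        thermo_table: ThermoTable | None = None,
        parent_ems: EMSet | None = None,
        protected: Iterable[str] | None = None,
        reenumerate: bool = False,
    ):
        cfg.validate()
        if cfg.weighting_scheme == "thermodynamic" and thermo_table is None:
            raise ValueError("thermodynamic weighting requires a ThermoTable")
        self.model = model
        self.cfg = cfg
        self.thermo_table = thermo_table
        self.ems = parent_ems if parent_ems is not None else enumerate_efms(model)
        self.protected = (
            set(protected) if protected is not None
            else essential_reactions(model, self.ems)
        )
        self.deletable = [r.id for r in model.reactions if r.id not in self.protected]
        self.theoretical_product = max_yield(self.ems, model, "product")["value"]
        self.theoretical_biomass = max_yield(self.ems, model, "biomass")["value"]
        self.reenumerate = reenumerate
        self._cache: dict[tuple[int, ...], FitnessRecord] = {}
        self.n_evaluations = 0

    @property
    def n_bits(self) -> int:
        return len(self.deletable)

    def removed_reactions(self, bits: Sequence[int]) -> list[str]:
        return [rid for rid, b in zip(self.deletable, bits) if not b]

    def evaluate(self, bits: Sequence[int]) -> FitnessRecord:
        key = tuple(int(b) for b in bits)
        if len(key) != self.n_bits:
            raise ValueError(
                f"chromosome length {len(key)} != deletable reactions {self.n_bits}"
            )
        if key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1
        removed = self.removed_reactions(key)
        if self.reenumerate:
            sub = apply_knockouts(self.model, key, self.protected)
            surviving = enumerate_efms(sub)
            # map back onto parent reaction order for weighting
        else:
            surviving = self.ems.filter_knockouts(removed)
        record = self._score(surviving, n_removals=len(removed))
        self._cache[key] = record
        return record

    def _score(self, surviving: EMSet, n_removals: int) -> FitnessRecord:
        if not len(surviving):
            return FitnessRecord(0.0, 0.0, 0, n_removals)
        if self.cfg.weighting_scheme == "equal":
            weights: WeightVector = equal_weights(len(surviving))
        else:
            weights = thermo_weights(
                surviving, self.thermo_table, self.model, T=self.cfg.temperature
            )
            if weights.all_infeasible:
                return FitnessRecord(0.0, 0.0, len(surviving), n_removals)
        y = weighted_yields(surviving, weights, self.model)
        pf = (
            y["product_yield_mass"] / self.theoretical_product
            if self.theoretical_product > 0 else 0.0
        )
        bf = (
            y["biomass_flux_per_substrate"] / self.theoretical_biomass
            if self.theoretical_biomass > 0 else 0.0
        )
        # reversible product/biomass reactions can run backward in a mode;
        # clip so fitness stays in [0, 1]
        pf = min(max(pf, 0.0), 1.0)
        bf = min(max(bf, 0.0), 1.0)
        return FitnessRecord(pf, bf, len(surviving), n_removals)

    def chromosome(self, bits: Sequence[int]) -> Chromosome:
        rec = self.evaluate(bits)
        return Chromosome(tuple(int(b) for b in bits), rec.fitness(self.cfg.fitness), rec)


def evaluate_strain(
    bits: Sequence[int],
    parent: StoichiometricModel,
    cfg: GAConfig,
    thermo_table: ThermoTable | None = None,
    **kwargs,
) -> FitnessRecord:
    """One-shot strain evaluation (builds a fresh evaluator; see
    :class:`StrainEvaluator` for the cached batch interface)."""
    return StrainEvaluator(parent, cfg, thermo_table, **kwargs).evaluate(bits)


# ---------------------------------------------------------------------------
# GA driver
# ---------------------------------------------------------------------------


@dataclass
class GAResult:
    best: Chromosome
    history: list[dict]
    protected: set[str]
    deletable: list[str]
    n_evaluations: int
    terminated: str

    def removed_reactions(self) -> list[str]:
        return [rid for rid, b in zip(self.deletable, self.best.bits) if not b]


def _seed_population(rng, n_bits: int, cfg: GAConfig) -> list[tuple[int, ...]]:
    lo, hi = cfg.initial_knockouts_range
    pop = []
    for _ in range(cfg.population_size):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, n_bits)
        bits = [1] * n_bits
        for idx in rng.choice(n_bits, size=k, replace=False):
            bits[int(idx)] = 0
        pop.append(tuple(bits))
    return pop


def _select(rng, population: list[Chromosome], cfg: GAConfig) -> Chromosome:
    if cfg.selection == "tournament":
        idx = rng.integers(0, len(population), size=cfg.tournament_size)
        return max((population[int(i)] for i in idx), key=lambda c: c.fitness)
    # roulette: fitness-proportional; degenerate all-zero fitness -> uniform
    fit = np.array([c.fitness for c in population])
    total = fit.sum()
    if total <= 0:
        return population[int(rng.integers(0, len(population)))]
    return population[int(rng.choice(len(population), p=fit / total))]


def _two_point_crossover(rng, a: tuple[int, ...], b: tuple[int, ...]):
    n = len(a)
    if n < 2:
        return a
    i, j = sorted(int(x) for x in rng.integers(0, n + 1, size=2))
    return a[:i] + b[i:j] + a[j:]


def _mutate(rng, bits: tuple[int, ...], rate: float) -> tuple[int, ...]:
    if rate <= 0:
        return bits
    flips = rng.random(len(bits)) < rate
    return tuple(1 - b if f else b for b, f in zip(bits, flips))


def run_ga(
    parent: StoichiometricModel,
    cfg: GAConfig,
    thermo_table: ThermoTable | None = None,
    evaluator: StrainEvaluator | None = None,
) -> GAResult:
    """Evolve knockout genotypes toward the configured fitness optimum.

    Elitist generational GA: the ``elite_count`` best individuals pass to
    the next generation unchanged (so the best fitness is non-decreasing),
    the rest are produced by selection, two-point crossover and uniform
    per-bit mutation.  Terminates when the best fitness has changed by less
    than ``stall_tolerance`` (relative) over ``stall_generations``
    consecutive generations, or at ``max_generations``.
    """
    cfg.validate()
    ev = evaluator if evaluator is not None else StrainEvaluator(
        parent, cfg, thermo_table
    )
    rng = np.random.default_rng(cfg.rng_seed)
    population = [ev.chromosome(b) for b in _seed_population(rng, ev.n_bits, cfg)]
    history: list[dict] = []
    best_trace: list[float] = []
    terminated = "max_generations"
    for gen in range(cfg.max_generations):
        population.sort(key=lambda c: c.fitness, reverse=True)
        fits = [c.fitness for c in population]
        history.append(
            {"generation": gen, "best": fits[0], "mean": float(np.mean(fits))}
        )
        best_trace.append(fits[0])
        if len(best_trace) > cfg.stall_generations:
            prev = best_trace[-cfg.stall_generations - 1]
            cur = best_trace[-1]
            denom = abs(prev) if prev != 0 else 1.0
            if (cur - prev) / denom < cfg.stall_tolerance:
                terminated = "stall"
                break
        elites = population[: cfg.elite_count]
        offspring: list[Chromosome] = []
        while len(offspring) < cfg.population_size - cfg.elite_count:
            p1 = _select(rng, population, cfg)
            if rng.random() < cfg.crossover_fraction:
                p2 = _select(rng, population, cfg)
                child_bits = _two_point_crossover(rng, p1.bits, p2.bits)
            else:
                child_bits = p1.bits
            child_bits = _mutate(rng, child_bits, cfg.mutation_rate)
            offspring.append(ev.chromosome(child_bits))
        population = elites + offspring
    population.sort(key=lambda c: c.fitness, reverse=True)
    return GAResult(
        best=population[0],
        history=history,
        protected=set(ev.protected),
        deletable=list(ev.deletable),
        n_evaluations=ev.n_evaluations,
        terminated=terminated,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def exhaustive_search(
    parent: StoichiometricModel,
    max_knockouts: int,
    cfg: GAConfig | None = None,
    thermo_table: ThermoTable | None = None,
    evaluator: StrainEvaluator | None = None,
) -> Chromosome:
    """Evaluate every knockout combination up to ``max_knockouts``.

    Returns the argmax chromosome; ties break deterministically toward the
    lexicographically first combination at the smallest knockout count.
    Refuses if the number of combinations exceeds 10**6.
    """
    cfg = cfg if cfg is not None else GAConfig()
    ev = evaluator if evaluator is not None else StrainEvaluator(
        parent, cfg, thermo_table
    )
    n = ev.n_bits
    k_max = min(max_knockouts, n)
    n_combos = sum(comb(n, k) for k in range(k_max + 1))
    if n_combos > _EXHAUSTIVE_BUDGET:
        raise ValueError(
            f"{n_combos} combinations exceed the exhaustive budget {_EXHAUSTIVE_BUDGET}"
        )
    best: Chromosome | None = None
    for k in range(k_max + 1):
        for combo in itertools.combinations(range(n), k):
            bits = [1] * n
            for idx in combo:
                bits[idx] = 0
            cand = ev.chromosome(bits)
            if best is None or cand.fitness > best.fitness:
                best = cand
    assert best is not None
    return best
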