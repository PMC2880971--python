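"""Multi-objective knockout search: Pareto front of product vs. biomass.

Instead of collapsing product and biomass yield fractions into one scalar,
the multi-objective GA maximizes the pair (product_fraction,
biomass_fraction) and returns the set of non-inferior (Pareto-optimal)
strains: those for which improving one objective requires worsening the
other.  The search is a controlled-elitist variant of NSGA-II — fast
non-dominated sorting with crowding-distance diversity preservation, with
the fraction of front-1 individuals carried into the next generation capped
(default 0.35) so later fronts retain representation.

Termination is a generation cap (default 200) since the underlying
convergence criterion of a scalar GA does not apply to a front; the cap is
recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .ga import (
    Chromosome,
    GAConfig,
    StrainEvaluator,
    _mutate,
    _seed_population,
    _two_point_crossover,
)
from .model_io import StoichiometricModel
from .thermo import ThermoTable

MOGA_POPULATION_DEFAULT = 200
MOGA_GENERATIONS_DEFAULT = 200
PARETO_FRACTION_DEFAULT = 0.35


def dominance_filter(points: Sequence[tuple[float, float]]) -> list[int]:
    """Indices of the non-dominated points, in stable input order.

    Point a dominates b iff a >= b on both objectives and a > b on at least
    one.  Duplicated non-dominated points are all retained.
    """
    pts = [tuple(p) for p in points]
    keep = []
    for i, p in enumerate(pts):
        dominated = any(
            q[0] >= p[0] and q[1] >= p[1] and (q[0] > p[0] or q[1] > p[1])
            for j, q in enumerate(pts)
            if j != i
        )
        if not dominated:
            keep.append(i)
    return keep


def fast_non_dominated_sort(objs: list[tuple[float, float]]) -> list[list[int]]:
    """Deb's fast non-dominated sort; returns fronts of indices (front 0 best)."""
    n = len(objs)
    S = [[] for _ in range(n)]
    counts = [0] * n
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(objs[p], objs[q]):
                S[p].append(q)
            elif _dominates(objs[q], objs[p]):
                counts[p] += 1
        if counts[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt = []
        for p in fronts[i]:
            for q in S[p]:
                counts[q] -= 1
                if counts[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    fronts.pop()
    return fronts


def _dominates(a, b) -> bool:
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def crowding_distance(objs: list[tuple[float, float]], front: list[int]) -> dict[int, float]:
    dist = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: float("inf") for i in front}
    for dim in (0, 1):
        order = sorted(front, key=lambda i: objs[i][dim])
        lo, hi = objs[order[0]][dim], objs[order[-1]][dim]
        dist[order[0]] = dist[order[-1]] = float("inf")
        span = hi - lo
        if span <= 0:
            continue
        for rank in range(1, len(order) - 1):
            prev_v = objs[order[rank - 1]][dim]
            next_v = objs[order[rank + 1]][dim]
            dist[order[rank]] += (next_v - prev_v) / span
    return dist


def hypervolume_2d(points: Sequence[tuple[float, float]],
                   reference: tuple[float, float] = (0.0, 0.0)) -> float:
    """Dominated hypervolume (area) of a 2-D maximization front."""
    keep = dominance_filter(points)
    front = sorted({tuple(points[i]) for i in keep}, key=lambda p: -p[0])
    area = 0.0
    prev_y = reference[1]
    for x, y in front:
        if x <= reference[0] or y <= prev_y:
            continue
        area += (x - reference[0]) * (y - prev_y)
        prev_y = y
    return area


@dataclass
class ParetoFront:
    """Non-inferior strains with their objective pairs.

    ``members`` is sorted by product_fraction descending; no member
    dominates another.  ``final_population`` (chromosome, objectives) allows
    front-fraction statistics on the terminal generation.
    """

    members: list[tuple[Chromosome, float, float]]
    generations: int
    final_population: list[tuple[Chromosome, float, float]] = field(default_factory=list)
    hypervolume_history: list[float] = field(default_factory=list)
    terminated: str = "generation_cap"

    def objective_pairs(self) -> list[tuple[float, float]]:
        return [(p, b) for _, p, b in self.members]

    @property
    def front_fraction(self) -> float:
        """Fraction of the final population lying on the front."""
        if not self.final_population:
            return 0.0
        member_bits = {c.bits for c, _, _ in self.members}
        on_front = sum(1 for c, _, _ in self.final_population if c.bits in member_bits)
        return on_front / len(self.final_population)


def _objectives(ev: StrainEvaluator, bits) -> tuple[Chromosome, float, float]:
    rec = ev.evaluate(bits)
    return (
        Chromosome(tuple(int(b) for b in bits), rec.coupled, rec),
        rec.product_fraction,
        rec.biomass_fraction,
    )


def run_moga(
    parent: StoichiometricModel,
    cfg: GAConfig | None = None,
    thermo_table: ThermoTable | None = None,
    evaluator: StrainEvaluator | None = None,
    max_generations: int = MOGA_GENERATIONS_DEFAULT,
    pareto_fraction: float = PARETO_FRACTION_DEFAULT,
) -> ParetoFront:
    """NSGA-II style multi-objective knockout search.

    ``cfg`` reuses :class:`~emdesign.ga.GAConfig` for the variation
    operators and seeding; the population defaults to 200 individuals.
    Controlled elitism caps front-1 survivors at ``pareto_fraction`` of the
    population when later fronts still have candidates.
    """
    if cfg is None:
        cfg = GAConfig(population_size=MOGA_POPULATION_DEFAULT)
    cfg.validate()
    ev = evaluator if evaluator is not None else StrainEvaluator(
        parent, cfg, thermo_table
    )
    rng = np.random.default_rng(cfg.rng_seed)
    pop_bits = _seed_population(rng, ev.n_bits, cfg)
    population = [_objectives(ev, b) for b in pop_bits]
    hv_history: list[float] = []
    for gen in range(max_generations):
        objs = [(p, b) for _, p, b in population]
        hv_history.append(hypervolume_2d(objs))
        offspring_bits = _make_offspring(rng, population, objs, cfg)
        combined = population + [_objectives(ev, b) for b in offspring_bits]
        population = _environmental_selection(
            combined, cfg.population_size, pareto_fraction
        )
    objs = [(p, b) for _, p, b in population]
    hv_history.append(hypervolume_2d(objs))
    front_idx = dominance_filter(objs)
    seen_bits = set()
    members = []
    for i in front_idx:
        c, p, b = population[i]
        if c.bits in seen_bits:
            continue
        seen_bits.add(c.bits)
        members.append((c, p, b))
    members.sort(key=lambda t: (-t[1], -t[2]))
    return ParetoFront(
        members=members,
        generations=max_generations,
        final_population=population,
        hypervolume_history=hv_history,
    )


def _make_offspring(rng, population, objs, cfg: GAConfig) -> list[tuple[int, ...]]:
    fronts = fast_non_dominated_sort(objs)
    rank = {}
    crowd = {}
    for fi, front in enumerate(fronts):
        cd = crowding_distance(objs, front)
        for i in front:
            rank[i] = fi
            crowd[i] = cd[i]

    def binary_tournament() -> int:
        i, j = (int(x) for x in rng.integers(0, len(population), size=2))
        if rank[i] != rank[j]:
            return i if rank[i] < rank[j] else j
        return i if crowd[i] >= crowd[j] else j

    offspring = []
    while len(offspring) < cfg.population_size:
        a = population[binary_tournament()][0].bits
        if rng.random() < cfg.crossover_fraction:
            b = population[binary_tournament()][0].bits
            child = _two_point_crossover(rng, a, b)
        else:
            child = a
        offspring.append(_mutate(rng, child, cfg.mutation_rate))
    return offspring


def _environmental_selection(combined, pop_size: int, pareto_fraction: float):
    objs = [(p, b) for _, p, b in combined]
    fronts = fast_non_dominated_sort(objs)
    front1_cap = max(1, ceil(pareto_fraction * pop_size))

    selected: list[int] = []
    for fi, front in enumerate(fronts):
        cap = pop_size - len(selected)
        if fi == 0 and len(fronts) > 1:
            cap = min(cap, front1_cap) if len(front) > front1_cap else cap
        if len(front) <= cap:
            selected.extend(front)
        else:
            cd = crowding_distance(objs, front)
            ordered = sorted(front, key=lambda i: -cd[i])
            selected.extend(ordered[:cap])
        if len(selected) >= pop_size:
            break
    # if controlled elitism truncated front 1 but later fronts were empty,
    # refill from front 1 by crowding distance
    if len(selected) < pop_size:
        cd = crowding_distance(objs, fronts[0])
        extra = [i for i in sorted(fronts[0], key=lambda i: -cd[i])
                 if i not in set(selected)]
        selected.extend(extra[: pop_size - len(selected)])
    return [combined[i] for i in selected[:pop_size]]
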