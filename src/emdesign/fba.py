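"""Flux balance analysis: LP flux determination for comparison with EM weighting.

FBA fixes the substrate uptake to 1 and maximizes a single objective flux
(typically biomass) subject to S·v = 0 and capacity bounds: reversible
reactions default to [−10, 10] and irreversible ones to [0, 10] (arbitrary
units).  With uptake fixed and non-binding capacity bounds, the optimum is
attained on an extreme ray of the flux cone, so the objective per unit
substrate equals the best per-substrate yield over the elementary modes —
the cross-module oracle the test suite exercises.

Degenerate alternate optima are possible; one solver vertex is reported, so
reaction-wise comparisons against EM-weighted fluxes should be read with
that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_io import StoichiometricModel
from .thermo import FluxVector

DEFAULT_CAP = 10.0


class InfeasibleLPError(RuntimeError):
    """The FBA linear program has no feasible flux distribution."""


@dataclass
class FluxBounds:
    """Per-reaction lower/upper flux bounds (arbitrary units)."""

    lower: dict[str, float]
    upper: dict[str, float]

    @classmethod
    def default(
        cls,
        model: StoichiometricModel,
        cap: float = DEFAULT_CAP,
        substrate_uptake: float = 1.0,
    ) -> "FluxBounds":
        """Paper-style defaults: rev [−cap, cap], irrev [0, cap], uptake fixed."""
        lower, upper = {}, {}
        for r in model.reactions:
            lower[r.id] = -cap if r.reversible else 0.0
            upper[r.id] = cap
        lower[model.substrate_rxn] = substrate_uptake
        upper[model.substrate_rxn] = substrate_uptake
        return cls(lower, upper)

    def validate(self, model: StoichiometricModel) -> None:
        for r in model.reactions:
            a, b = self.lower[r.id], self.upper[r.id]
            if a > b:
                raise ValueError(f"bounds for {r.id!r} inverted: [{a}, {b}]")
            if not r.reversible and a < 0:
                raise ValueError(f"irreversible {r.id!r} has negative lower bound")

    def override(self, rows: dict[str, tuple[float, float]]) -> "FluxBounds":
        lower = dict(self.lower)
        upper = dict(self.upper)
        for rid, (a, b) in rows.items():
            lower[rid], upper[rid] = a, b
        return FluxBounds(lower, upper)


@dataclass
class FBAResult:
    fluxes: FluxVector
    objective_value: float
    status: str


def fba_fluxes(
    model: StoichiometricModel,
    bounds: FluxBounds | None = None,
    objective_rxn: str | None = None,
) -> FBAResult:
    """Maximize the objective flux subject to S·v = 0 and the bounds.

    Defaults: objective = the model's biomass reaction; bounds =
    :meth:`FluxBounds.default` with the substrate uptake fixed to 1.
    Raises :class:`InfeasibleLPError` on an infeasible program rather than
    silently returning zeros.
    """
    if objective_rxn is None:
        objective_rxn = model.biomass_rxn
    if objective_rxn not in model.reaction_ids:
        raise ValueError(f"objective reaction {objective_rxn!r} not in model")
    if bounds is None:
        bounds = FluxBounds.default(model)
    bounds.validate(model)

    S = model.stoich_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index(objective_rxn)] = -1.0  # linprog minimizes
    lp_bounds = [
        (bounds.lower[r.id], bounds.upper[r.id]) for r in model.reactions
    ]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=lp_bounds,
        method="highs",
    )
    if not res.success:
        raise InfeasibleLPError(f"FBA LP failed: {res.message}")
    v = FluxVector(res.x, list(model.reaction_ids))
    return FBAResult(fluxes=v, objective_value=-res.fun, status=res.message)
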