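"""Pathway Gibbs energies, thermodynamic EM weighting, and flux reconstruction.

Each reaction's standard Gibbs energy change ΔGr° (kcal/mol) is either
supplied directly or computed as the stoichiometric sum of metabolite
formation energies ΔGf°, including currency species that may be absent from
the balanced stoichiometric matrix.  A mode's pathway energy ΔGp° is the
coefficient-weighted sum of ΔGr° over its support (a reversible reaction used
backward contributes −ΔGr°), evaluated on modes normalized to unit substrate
uptake so the weighting is invariant to arbitrary mode scaling.

Flux reconstruction takes v = M·c, a convex combination of the EM matrix
columns with weights c, Σc = 1.  Two weighting schemes are provided:

* ``equal``: c_i = 1/n.
* ``thermodynamic``: Boltzmann weights c_i ∝ exp(−ΔGp°_i / RT) for feasible
  modes (ΔGp° ≤ 0); thermodynamically infeasible modes (ΔGp° > 0) receive
  weight 0.  R = 1.9872e-3 kcal mol⁻¹ K⁻¹, T defaults to 310.15 K (37 °C).

The exponential form is isolated behind :func:`boltzmann_policy` so an
alternative monotone weighting law can be swapped without touching callers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .efm import EMSet, ElementaryMode
from .model_io import ConfigError, Reaction, StoichiometricModel

R_KCAL = 1.9872e-3  # kcal / (mol K)
T_DEFAULT = 310.15  # K


@dataclass
class ThermoTable:
    """ΔGf° per metabolite and/or ΔGr° per reaction, kcal/mol.

    Directly supplied ΔGr° values take precedence over values derived from
    formation energies.  ``extra_stoich`` lets a reaction's Gibbs bookkeeping
    include currency metabolites (ATP, NAD(P)H, ...) that the balanced S
    matrix omits.
    """

    dGf: dict[str, float] = field(default_factory=dict)
    dGr: dict[str, float] = field(default_factory=dict)
    extra_stoich: dict[str, dict[str, float]] = field(default_factory=dict)

    def reaction_dG(self, rxn: Reaction) -> float:
        """ΔGr° = Σ ν_i ΔGf°_i (products positive, substrates negative)."""
        if rxn.id in self.dGr:
            return self.dGr[rxn.id]
        total = 0.0
        stoich: dict[str, float] = {m: float(c) for m, c in rxn.stoichiometry.items()}
        for met, coeff in self.extra_stoich.get(rxn.id, {}).items():
            stoich[met] = stoich.get(met, 0.0) + coeff
        for met, coeff in stoich.items():
            if met not in self.dGf:
                raise ConfigError(
                    f"no ΔGf° for species {met!r} (reaction {rxn.id!r})"
                )
            total += coeff * self.dGf[met]
        return total

    def ensure_reaction_dGs(self, model: StoichiometricModel) -> dict[str, float]:
        """ΔGr° for every model reaction (direct values win over derived)."""
        return {r.id: self.reaction_dG(r) for r in model.reactions}


def reaction_dG(table: ThermoTable, rxn: Reaction) -> float:
    return table.reaction_dG(rxn)


def pathway_dG(
    em: ElementaryMode, dGr: Mapping[str, float]
) -> float:
    """ΔGp° = Σ_j e_j ΔGr°_j over the mode's support (signed coefficients)."""
    total = 0.0
    for rid, coeff in zip(em.reaction_ids, em.coeffs):
        if coeff != 0:
            if rid not in dGr:
                raise ConfigError(f"no ΔGr° for reaction {rid!r}")
            total += float(coeff) * dGr[rid]
    return total


def pathway_dGs(ems: EMSet, table: ThermoTable, model: StoichiometricModel) -> np.ndarray:
    dGr = table.ensure_reaction_dGs(model)
    return np.array([pathway_dG(m, dGr) for m in ems])


def feasibility_census(
    ems: EMSet, table: ThermoTable, model: StoichiometricModel
) -> dict:
    """Count thermodynamically infeasible modes (ΔGp° > 0)."""
    dgp = pathway_dGs(ems, table, model)
    n_inf = int(np.sum(dgp > 0.0))
    n = len(ems)
    return {
        "n_total": n,
        "n_infeasible": n_inf,
        "fraction": (n_inf / n) if n else 0.0,
        "dGp_mean": float(np.mean(dgp)) if n else float("nan"),
        "dGp_median": float(np.median(dgp)) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Weight vectors
# ---------------------------------------------------------------------------


@dataclass
class WeightVector:
    c: np.ndarray
    scheme: str
    all_infeasible: bool = False

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)

    def __len__(self) -> int:
        return len(self.c)


def equal_weights(n: int) -> WeightVector:
    """c_i = 1/n (no thermodynamic filtering under equal weighting)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return WeightVector(np.zeros(0), "equal")
    return WeightVector(np.full(n, 1.0 / n), "equal")


def boltzmann_policy(dgp: np.ndarray, T: float) -> np.ndarray:
    """Unnormalized weights: exp(−ΔGp°/RT) for feasible modes, 0 otherwise.

    Exponents are shifted by their maximum before exponentiation; the shift
    cancels in the subsequent normalization, avoiding overflow for strongly
    exergonic pathways.
    """
    feasible = dgp <= 0.0
    exponents = np.where(feasible, -dgp / (R_KCAL * T), -np.inf)
    if not np.any(feasible):
        return np.zeros_like(dgp)
    shifted = exponents - np.max(exponents[feasible])
    raw = np.where(feasible, np.exp(shifted), 0.0)
    return raw


def thermo_weights(
    ems: EMSet,
    table: ThermoTable,
    model: StoichiometricModel,
    T: float = T_DEFAULT,
    policy: Callable[[np.ndarray, float], np.ndarray] = boltzmann_policy,
) -> WeightVector:
    """Thermodynamic weighting of the EMs (normalized to Σc = 1).

    If every mode is infeasible the zero vector is returned with
    ``all_infeasible`` set, and downstream strain fitness becomes 0.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not len(ems):
        return WeightVector(np.zeros(0), "thermodynamic", all_infeasible=True)
    dgp = pathway_dGs(ems, table, model)
    raw = policy(dgp, T)
    total = raw.sum()
    if total <= 0.0:
        return WeightVector(np.zeros(len(ems)), "thermodynamic", all_infeasible=True)
    return WeightVector(raw / total, "thermodynamic")


@dataclass
class FluxVector:
    v: np.ndarray
    reaction_ids: list[str]

    def __getitem__(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])

    def as_series(self):
        import pandas as pd

        return pd.Series(self.v, index=self.reaction_ids, name="flux")


def reconstruct_flux(ems: EMSet, c: WeightVector | np.ndarray) -> FluxVector:
    """v = M·c: the weighted linear combination of the elementary modes."""
    weights = c.c if isinstance(c, WeightVector) else np.asarray(c, dtype=float)
    if len(weights) != len(ems):
        raise ValueError(
            f"weight vector length {len(weights)} != number of modes {len(ems)}"
        )
    if not len(ems):
        return FluxVector(np.zeros(len(ems.reaction_ids)), list(ems.reaction_ids))
    return FluxVector(ems.matrix @ weights, list(ems.reaction_ids))


def weighted_yields(
    ems: EMSet, c: WeightVector | np.ndarray, model: StoichiometricModel
) -> dict[str, float]:
    """Strain yields under weight vector c.

    Computed as the c-weighted average of per-mode yields with modes
    normalized to unit substrate uptake; modes with zero substrate uptake
    participate in the weighting but contribute zero yield by convention.
    Equals the yields read off v = M·c whenever every weighted mode consumes
    substrate.
    """
    from .efm import mode_yields

    weights = c.c if isinstance(c, WeightVector) else np.asarray(c, dtype=float)
    yp = yb = 0.0
    for w, m in zip(weights, ems.modes):
        if w == 0.0:
            continue
        y = mode_yields(m, model)
        yp += w * y["product_yield_mass"]
        yb += w * y["biomass_flux_per_substrate"]
    return {"product_yield_mass": yp, "biomass_flux_per_substrate": yb}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_dgf_csv(path) -> dict[str, float]:
    """Read `metabolite,dGf_kcal_mol` CSV into a formation-energy map."""
    return _load_two_col(path, key_field=("metabolite", "species"))


def load_dgr_csv(path) -> dict[str, float]:
    """Read `reaction,dGr_kcal_mol` CSV into a reaction-energy map."""
    return _load_two_col(path, key_field=("reaction",))


def _load_two_col(path, key_field) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(str(path), newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and any(k in row[0].lower() for k in key_field):
                continue  # header
            out[row[0].strip()] = float(row[1])
    return out


def load_mw_csv(path) -> dict[str, float]:
    """Read `species,mw_g_per_mol` CSV."""
    out: dict[str, float] = {}
    with open(str(path), newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and "species" in row[0].lower():
                continue
            out[row[0].strip()] = float(row[1])
    return out
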