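"""Elementary flux mode enumeration, classification, and per-mode yields.

An elementary flux mode (EM) is a minimal steady-state flux vector of the
network: S·e = 0 over internal metabolites, e_j ≥ 0 on irreversible
reactions, and no other steady-state vector has a support that is a proper
subset of e's (equivalently, the EMs are the extreme rays of the flux cone
after reversible reactions are split into irreversible direction pairs).

Enumeration here uses the classical double-description (tableau) algorithm:
reversible reactions are split, the steady-state constraints are imposed one
internal metabolite at a time by combining positive/negative candidate pairs,
and non-minimal supports are pruned at every step.  Arithmetic is exact
(:class:`fractions.Fraction`), so the S·e = 0 and elementarity checks are
rank decisions without tolerance.  A brute-force enumerator over candidate
supports serves as an independent oracle for small networks.

Conventions
-----------
* Spurious two-cycles (forward+backward of one split reversible reaction)
  are removed; surviving modes are folded back to signed coefficients.
* A mode whose support is entirely reversible is reported once, with the
  sign chosen so its first nonzero coefficient (model reaction order) is
  positive — except that substrate-consuming modes are flipped to positive
  substrate flux first.
* Normalization: substrate flux scaled to 1 when positive, otherwise
  max|coefficient| = 1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import ConfigError, StoichiometricModel

PRODUCES_TOL = 1e-9  # floor on "produces X" for float-backed modes
YIELD_REL_TOL = 1e-6  # relative tolerance for "attains the maximum yield"

_BRUTE_FORCE_MAX_SPLIT = 18


@dataclass(frozen=True)
class ElementaryMode:
    """One elementary mode: signed rational coefficients over model reactions."""

    coeffs: tuple[Fraction, ...]
    reaction_ids: tuple[str, ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(
            rid for rid, c in zip(self.reaction_ids, self.coeffs) if c != 0
        )

    @property
    def support_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.coeffs) if c != 0)

    def coeff(self, rid: str) -> Fraction:
        return self.coeffs[self.reaction_ids.index(rid)]

    def as_float(self) -> np.ndarray:
        return np.array([float(c) for c in self.coeffs])


@dataclass
class EMSet:
    """The complete set of elementary modes of a model.

    ``matrix`` is the EM matrix M whose columns are the modes; the flux
    vector of any admissible steady state is M·c for some weight vector c.
    """

    modes: list[ElementaryMode]
    reaction_ids: list[str]
    model_name: str = ""

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    @property
    def matrix(self) -> np.ndarray:
        if not self.modes:
            return np.zeros((len(self.reaction_ids), 0))
        return np.column_stack([m.as_float() for m in self.modes])

    def supports(self) -> set[frozenset[str]]:
        return {m.support for m in self.modes}

    def filter_knockouts(self, removed: Iterable[str]) -> "EMSet":
        """Modes surviving removal of ``removed`` reactions.

        By the knockout-subset property, the EM set of a deletion strain is
        exactly the subset of parent modes whose supports avoid the removed
        reactions; no re-enumeration is required.
        """
        removed = set(removed)
        kept = [m for m in self.modes if not (m.support & removed)]
        return EMSet(kept, list(self.reaction_ids), self.model_name + "+ko")


@dataclass(frozen=True)
class ModeCensus:
    n_total: int
    n_product: int
    n_biomass: int
    n_both: int

    def as_dict(self) -> dict:
        pct = lambda k: round(100.0 * k / self.n_total, 1) if self.n_total else 0.0
        return {
            "n_total": self.n_total,
            "n_product": self.n_product,
            "n_biomass": self.n_biomass,
            "n_both": self.n_both,
            "pct_product": pct(self.n_product),
            "pct_biomass": pct(self.n_biomass),
            "pct_both": pct(self.n_both),
        }


# ---------------------------------------------------------------------------
# Split-network construction
# ---------------------------------------------------------------------------


def _split_network(model: StoichiometricModel):
    """Split reversible reactions into forward/backward irreversible columns.

    Returns (columns, origin) where ``columns`` are rational stoichiometry
    vectors over internal metabolites and ``origin[j] = (reaction_index,
    direction)`` with direction +1/-1.
    """
    S = model.stoich_rational()
    n_mets = len(S)
    columns: list[tuple[Fraction, ...]] = []
    origin: list[tuple[int, int]] = []
    for j, rxn in enumerate(model.reactions):
        col = tuple(S[i][j] for i in range(n_mets))
        columns.append(col)
        origin.append((j, +1))
        if rxn.reversible:
            columns.append(tuple(-c for c in col))
            origin.append((j, -1))
    return columns, origin


def _normalize_integer(vec: list[Fraction]) -> tuple[Fraction, ...]:
    """Scale a rational vector to coprime integers (keeps tableaux small)."""
    denoms = [c.denominator for c in vec if c != 0]
    if not denoms:
        return tuple(vec)
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(c * lcm) for c in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    return tuple(Fraction(v, g) for v in ints)


def _tableau_enumerate(columns, n_mets: int) -> list[tuple[Fraction, ...]]:
    """Double-description pass over internal metabolites.

    Candidates are (flux-over-split-reactions, residual S·v) pairs; each
    metabolite constraint keeps the zero-residual rows and all minimal-support
    positive/negative combinations.
    """
    n = len(columns)
    rows = []
    for j in range(n):
        flux = [Fraction(0)] * n
        flux[j] = Fraction(1)
        rows.append((tuple(flux), tuple(columns[j])))

    for m in range(n_mets):
        zeros, pos, neg = [], [], []
        for flux, resid in rows:
            r = resid[m]
            if r == 0:
                zeros.append((flux, resid))
            elif r > 0:
                pos.append((flux, resid))
            else:
                neg.append((flux, resid))
        combined = []
        for (fp, rp), (fn, rn) in itertools.product(pos, neg):
            a, b = -rn[m], rp[m]  # both positive
            flux = [a * x + b * y for x, y in zip(fp, fn)]
            resid = [a * x + b * y for x, y in zip(rp, rn)]
            # rescale flux and residual together so the pair stays consistent
            joint = _normalize_integer(flux + resid)
            combined.append((joint[: len(flux)], tuple(joint[len(flux):])))
        rows = _prune_nonminimal(zeros + combined, n)
    return [flux for flux, _ in rows]


def _prune_nonminimal(rows, n):
    """Drop rows whose support strictly contains another row's support."""
    entries = []
    for flux, resid in rows:
        bits = 0
        for j, c in enumerate(flux):
            if c != 0:
                bits |= 1 << j
        entries.append((bits, flux, resid))
    # dedupe exact duplicate rays only; equal supports with distinct rays
    # must both survive (they are resolved by later constraints)
    seen: set[tuple] = set()
    deduped = []
    for bits, flux, resid in entries:
        if flux not in seen:
            seen.add(flux)
            deduped.append((bits, flux, resid))
    deduped.sort(key=lambda e: bin(e[0]).count("1"))
    kept: list[tuple] = []
    kept_bits: list[int] = []
    for bits, flux, resid in deduped:
        if any(kb != bits and kb & bits == kb for kb in kept_bits):
            continue
        kept.append((flux, resid))
        kept_bits.append(bits)
    return kept


def _fold_and_canonicalize(
    split_vectors, origin, model: StoichiometricModel
) -> list[ElementaryMode]:
    """Fold split fluxes back to signed vectors; drop 2-cycles; normalize."""
    n_rxns = len(model.reactions)
    sub_idx = model.reaction_index(model.substrate_rxn)
    reversible = [r.reversible for r in model.reactions]
    rids = tuple(model.reaction_ids)

    out: dict[tuple, ElementaryMode] = {}
    for vec in split_vectors:
        signed = [Fraction(0)] * n_rxns
        touched_both: dict[int, set[int]] = {}
        for j, c in enumerate(vec):
            if c == 0:
                continue
            ridx, direction = origin[j]
            signed[ridx] += direction * c
            touched_both.setdefault(ridx, set()).add(direction)
        # spurious 2-cycle: support is exactly one reversible reaction both ways
        if len(touched_both) == 1:
            (ridx, dirs), = touched_both.items()
            if dirs == {+1, -1}:
                continue
        if all(c == 0 for c in signed):
            continue
        signed = _canonical_sign(signed, reversible, sub_idx)
        signed = _normalize_mode(signed, sub_idx)
        key = tuple(signed)
        if key not in out:
            out[key] = ElementaryMode(tuple(signed), rids)
    modes = list(out.values())
    modes.sort(key=lambda m: sorted(m.support))
    return modes


def _canonical_sign(signed, reversible, sub_idx):
    # A fully reversible support admits both orientations; pick one canonically.
    if all(reversible[j] for j, c in enumerate(signed) if c != 0):
        if signed[sub_idx] != 0:
            if signed[sub_idx] < 0:
                signed = [-c for c in signed]
        else:
            first = next(c for c in signed if c != 0)
            if first < 0:
                signed = [-c for c in signed]
    return signed


def _normalize_mode(signed, sub_idx):
    s = signed[sub_idx]
    if s > 0:
        return [c / s for c in signed]
    scale = max(abs(c) for c in signed if c != 0)
    return [c / scale for c in signed]


def enumerate_efms(model: StoichiometricModel) -> EMSet:
    """Enumerate the complete elementary-mode set of a validated model."""
    if not model.internal_metabolites:
        raise ConfigError("model has no internal metabolite; the flux cone is trivial")
    columns, origin = _split_network(model)
    n_mets = len(model.internal_metabolites)
    split_vectors = _tableau_enumerate(columns, n_mets)
    modes = _fold_and_canonicalize(split_vectors, origin, model)
    return EMSet(modes, list(model.reaction_ids), model.name)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _rational_nullspace(rows: list[list[Fraction]]) -> list[list[Fraction]]:
    """Nullspace basis of a rational matrix by Gaussian elimination."""
    if not rows:
        return []
    n = len(rows[0])
    mat = [list(r) for r in rows]
    pivots: list[int] = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, len(mat)) if mat[i][c] != 0), None)
        if pivot is None:
            continue
        mat[r], mat[pivot] = mat[pivot], mat[r]
        pv = mat[r][c]
        mat[r] = [x / pv for x in mat[r]]
        for i in range(len(mat)):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [x - f * y for x, y in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == len(mat):
            break
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for pr, pc in enumerate(pivots):
            v[pc] = -mat[pr][fc]
        basis.append(v)
    return basis


def rational_rank(rows: list[list[Fraction]]) -> int:
    if not rows or not rows[0]:
        return 0
    n = len(rows[0])
    return n - len(_rational_nullspace(rows))


def brute_force_efms(model: StoichiometricModel) -> EMSet:
    """Independent EM enumeration by exhaustive search over supports.

    For every candidate support of the split network, the support is kept iff
    the restricted nullspace is one-dimensional with a strictly positive
    generator and no kept support is a proper subset.  Exponential in the
    number of split reactions; guarded at 18 columns.
    """
    columns, origin = _split_network(model)
    n = len(columns)
    if n > _BRUTE_FORCE_MAX_SPLIT:
        raise ValueError(
            f"brute_force_efms is limited to {_BRUTE_FORCE_MAX_SPLIT} split "
            f"reactions; model has {n}"
        )
    n_mets = len(model.internal_metabolites)
    accepted_bits: list[int] = []
    accepted_vecs: list[tuple[Fraction, ...]] = []
    indices = list(range(n))
    for size in range(1, n + 1):
        for combo in itertools.combinations(indices, size):
            bits = 0
            for j in combo:
                bits |= 1 << j
            if any(kb & bits == kb for kb in accepted_bits):
                continue  # strict superset of an accepted support
            sub_rows = [[columns[j][i] for j in combo] for i in range(n_mets)]
            null = _rational_nullspace(sub_rows)
            if len(null) != 1:
                continue
            gen = null[0]
            if any(c == 0 for c in gen):
                continue  # support of generator smaller than candidate
            if all(c < 0 for c in gen):
                gen = [-c for c in gen]
            if any(c < 0 for c in gen):
                continue  # sign-infeasible in the pointed split cone
            full = [Fraction(0)] * n
            for j, c in zip(combo, gen):
                full[j] = c
            accepted_bits.append(bits)
            accepted_vecs.append(tuple(full))
    modes = _fold_and_canonicalize(accepted_vecs, origin, model)
    return EMSet(modes, list(model.reaction_ids), model.name)


# ---------------------------------------------------------------------------
# Elementarity / steady-state checks (used by the property tests)
# ---------------------------------------------------------------------------


def is_steady_state(mode: ElementaryMode, model: StoichiometricModel) -> bool:
    S = model.stoich_rational()
    for row in S:
        if sum(c * e for c, e in zip(row, mode.coeffs)) != 0:
            return False
    return True


def satisfies_irreversibility(mode: ElementaryMode, model: StoichiometricModel) -> bool:
    return all(
        mode.coeffs[j] >= 0
        for j, r in enumerate(model.reactions)
        if not r.reversible
    )


def is_elementary(mode: ElementaryMode, model: StoichiometricModel) -> bool:
    """rank(S restricted to the support) == |support| − 1, exactly."""
    S = model.stoich_rational()
    idx = mode.support_indices
    sub = [[row[j] for j in idx] for row in S]
    return rational_rank(sub) == len(idx) - 1


# ---------------------------------------------------------------------------
# Classification and yields
# ---------------------------------------------------------------------------


def classify_modes(ems: EMSet, model: StoichiometricModel) -> ModeCensus:
    """Count product-forming / biomass-forming / dual-forming modes."""
    ip = ems.reaction_ids.index(model.product_rxn)
    ib = ems.reaction_ids.index(model.biomass_rxn)
    n_p = n_b = n_both = 0
    for m in ems:
        p = float(m.coeffs[ip]) > PRODUCES_TOL
        b = float(m.coeffs[ib]) > PRODUCES_TOL
        n_p += p
        n_b += b
        n_both += p and b
    return ModeCensus(len(ems), n_p, n_b, n_both)


def mode_yields(em: ElementaryMode, model: StoichiometricModel) -> dict[str, float]:
    """Per-mode yields, per unit substrate uptake.

    ``product_yield_mass`` is (product flux × MW_product)/(substrate flux ×
    MW_substrate) in g/g; ``biomass_flux_per_substrate`` is the biomass
    reaction flux per unit substrate flux.  Modes with no substrate uptake
    score 0 on both by convention.
    """
    v_s = float(em.coeff(model.substrate_rxn))
    if v_s <= PRODUCES_TOL:
        return {"product_yield_mass": 0.0, "biomass_flux_per_substrate": 0.0}
    try:
        mw_s = model.mw["substrate"]
        mw_p = model.mw["product"]
    except KeyError as exc:
        raise ConfigError(f"molecular weight missing for {exc.args[0]!r}") from exc
    v_p = float(em.coeff(model.product_rxn))
    v_b = float(em.coeff(model.biomass_rxn))
    return {
        "product_yield_mass": (v_p * mw_p) / (v_s * mw_s),
        "biomass_flux_per_substrate": v_b / v_s,
    }


def _yield_of(em, model, target: str) -> float:
    y = mode_yields(em, model)
    return y["product_yield_mass"] if target == "product" else y[
        "biomass_flux_per_substrate"
    ]


def max_yield(ems: EMSet, model: StoichiometricModel, target: str = "product") -> dict:
    """Maximum per-mode yield, the modes attaining it, and isolation cost.

    Returns ``value``, ``n_modes_attaining`` (within relative tolerance
    1e-6), and ``knockouts_to_isolate`` — for each attaining mode, the number
    of reactions outside its support (removals needed to leave only that
    pathway).  Attaining modes are ordered by lexicographic support.
    """
    if target not in ("product", "biomass"):
        raise ValueError("target must be 'product' or 'biomass'")
    if not len(ems):
        return {"value": 0.0, "n_modes_attaining": 0, "knockouts_to_isolate": []}
    ys = [_yield_of(m, model, target) for m in ems]
    best = max(ys)
    if best <= 0:
        return {"value": max(best, 0.0), "n_modes_attaining": 0,
                "knockouts_to_isolate": []}
    attaining = [
        m for m, y in zip(ems.modes, ys) if y >= best * (1.0 - YIELD_REL_TOL)
    ]
    attaining.sort(key=lambda m: sorted(m.support))
    n_rxns = len(ems.reaction_ids)
    return {
        "value": best,
        "n_modes_attaining": len(attaining),
        "knockouts_to_isolate": [n_rxns - len(m.support) for m in attaining],
    }


# ---------------------------------------------------------------------------
# I/O: wide CSV of the EM matrix + census JSON
# ---------------------------------------------------------------------------


def emset_to_frame(ems: EMSet) -> pd.DataFrame:
    """Rows = reactions, columns = modes (EM1, EM2, ...)."""
    data = {
        f"EM{k + 1}": [float(c) for c in m.coeffs] for k, m in enumerate(ems.modes)
    }
    return pd.DataFrame(data, index=list(ems.reaction_ids))

def write_emset(ems: EMSet, csv_path, census: ModeCensus | None = None,
                census_path=None) -> None:
    emset_to_frame(ems).to_csv(csv_path, index_label="reaction")
    if census is not None and census_path is not None:
        with open(str(census_path), "w", encoding="utf-8") as fh:
            json.dump(census.as_dict(), fh, indent=2)


def read_emset(csv_path, model: StoichiometricModel) -> EMSet:
    """Read an externally computed EM matrix (wide CSV) for cross-validation."""
    df = pd.read_csv(csv_path, index_col=0)
    if list(df.index) != model.reaction_ids:
        raise ValueError("EM matrix rows do not match model reactions")
    rids = tuple(model.reaction_ids)
    modes = []
    for col in df.columns:
        coeffs = tuple(
            Fraction(v).limit_denominator(10**9) for v in df[col].tolist()
        )
        modes.append(ElementaryMode(coeffs, rids))
    return EMSet(modes, list(model.reaction_ids), model.name)
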