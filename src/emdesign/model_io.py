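"""Stoichiometric model containers, parsing, serialization, and toy fixtures.

A :class:`StoichiometricModel` holds the reaction network of a small metabolic
model: internal metabolites (balanced at steady state), external species
(sources/sinks, suffixed ``_ext`` in the TSV dialect), reaction stoichiometry
with reversibility flags and gene associations, and the three designated
reactions the strain-design workflow needs — substrate uptake, product
formation, and biomass synthesis.

Coefficients are stored as exact :class:`fractions.Fraction` values so that
downstream elementary-mode elementarity tests can make exact rank decisions;
floats on input are converted with a denominator limit of 10**6.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

EXTERNAL_SUFFIX = "_ext"
_COEFF_DENOM_LIMIT = 10**6


class ModelError(ValueError):
    """Raised for malformed or inconsistent model input."""


class ConfigError(ValueError):
    """Raised when a designated reaction or required table entry is missing."""


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x).limit_denominator(_COEFF_DENOM_LIMIT)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot convert {x!r} to a rational coefficient")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; internal metabolites are balanced at steady state."""

    id: str
    name: str = ""
    is_internal: bool = True


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed rational stoichiometry (products positive).

    ``genes`` lists the gene/operon labels associated one-to-one with the
    reaction for knockout reporting; it may be empty.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    genes: tuple[str, ...] = ()

    def __post_init__(self):
        stoich = {m: _as_fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not stoich:
            raise ModelError(f"reaction {self.id!r} has no nonzero coefficient")
        object.__setattr__(self, "stoichiometry", stoich)
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass
class StoichiometricModel:
    """A validated stoichiometric model with designated reaction roles.

    The stoichiometric matrix ``S`` has one row per *internal* metabolite and
    one column per reaction; external species never constrain the nullspace.
    ``mw`` maps species names (typically the substrate and product) to
    molecular weights in g/mol for mass-yield calculations.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    substrate_rxn: str
    product_rxn: str
    biomass_rxn: str
    mw: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if not rxn_ids:
            raise ModelError("model has no reactions")
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in known:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {m!r}"
                    )
        for role, rid in (
            ("substrate", self.substrate_rxn),
            ("product", self.product_rxn),
            ("biomass", self.biomass_rxn),
        ):
            if rid not in set(rxn_ids):
                raise ConfigError(f"designated {role} reaction {rid!r} not in model")

    # -- views ------------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.is_internal]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.reaction_index(rid)]

    def stoich_rational(self) -> list[list[Fraction]]:
        """S over internal metabolites as nested lists of exact Fractions."""
        rows = []
        for m in self.internal_metabolites:
            rows.append([r.stoichiometry.get(m.id, Fraction(0)) for r in self.reactions])
        return rows

    def stoich_matrix(self) -> np.ndarray:
        """S over internal metabolites as a float array (rows × reactions)."""
        return np.array(
            [[float(c) for c in row] for row in self.stoich_rational()], dtype=float
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.internal_metabolites), len(self.reactions))

    # -- submodels --------------------------------------------------------

    def subset(self, keep: Iterable[str], name: str | None = None) -> "StoichiometricModel":
        keep = set(keep)
        missing = keep - set(self.reaction_ids)
        if missing:
            raise ModelError(f"unknown reactions in subset: {sorted(missing)}")
        return StoichiometricModel(
            metabolites=list(self.metabolites),
            reactions=[r for r in self.reactions if r.id in keep],
            substrate_rxn=self.substrate_rxn,
            product_rxn=self.product_rxn,
            biomass_rxn=self.biomass_rxn,
            mw=dict(self.mw),
            name=name if name is not None else self.name + "+ko",
        )


def apply_knockouts(
    model: StoichiometricModel,
    chromosome: Sequence[int],
    protected: Iterable[str] = (),
) -> StoichiometricModel:
    """Build the deletion-strain submodel encoded by a binary chromosome.

    ``chromosome`` has one bit per *deletable* reaction (the model's reactions
    minus ``protected``, in model order); 1 keeps the reaction, 0 deletes it.
    Protected reactions are always retained.  The metabolite set is unchanged.
    """
    protected = set(protected)
    deletable = [r.id for r in model.reactions if r.id not in protected]
    if len(chromosome) != len(deletable):
        raise ValueError(
            f"chromosome length {len(chromosome)} != number of deletable "
            f"reactions {len(deletable)}"
        )
    keep = protected | {rid for rid, bit in zip(deletable, chromosome) if bit}
    return model.subset(keep)


# ---------------------------------------------------------------------------
# TSV dialect
#
#   # lines starting with '#' are directives or comments:
#   #substrate <TAB> RXN_ID
#   #product   <TAB> RXN_ID
#   #biomass   <TAB> RXN_ID
#   #mw        <TAB> species <TAB> value_g_per_mol
#   # data lines:  id <TAB> equation <TAB> reversible{0,1} <TAB> genes(comma-sep)
#
# Equation syntax: "2 A + B -> C" ("<->" marks a reversible reaction, which
# also sets the flag).  Metabolites suffixed "_ext" are external.
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)\s*$")


def _parse_side(side: str, sign: int, stoich: dict[str, Fraction], rxn_id: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelError(f"reaction {rxn_id!r}: cannot parse term {term!r}")
        coeff = _as_fraction(m.group(1)) if m.group(1) else Fraction(1)
        met = m.group(2)
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff


def parse_equation(equation: str, rxn_id: str = "?") -> tuple[dict[str, Fraction], bool]:
    """Parse ``2 A + B -> C`` into signed stoichiometry; ``<->`` ⇒ reversible."""
    if "<->" in equation:
        lhs, rhs = equation.split("<->", 1)
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->", 1)
        reversible = False
    else:
        raise ModelError(f"reaction {rxn_id!r}: equation missing '->': {equation!r}")
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich, rxn_id)
    _parse_side(rhs, +1, stoich, rxn_id)
    return {m: c for m, c in stoich.items() if c != 0}, reversible


def format_equation(rxn: Reaction) -> str:
    def side(items):
        parts = []
        for met, coeff in items:
            c = abs(coeff)
            parts.append(f"{c} {met}" if c != 1 else met)
        return " + ".join(parts)

    lhs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<->" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def loads_model(text: str, name: str = "") -> StoichiometricModel:
    """Parse the TSV dialect from a string."""
    substrate = product = biomass = None
    mw: dict[str, float] = {}
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = [f.strip() for f in line[1:].split("\t")]
            key = fields[0].lower()
            if key == "substrate":
                substrate = fields[1]
            elif key == "product":
                product = fields[1]
            elif key == "biomass":
                biomass = fields[1]
            elif key == "mw":
                mw[fields[1]] = float(fields[2])
            # other '#' lines are comments
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ModelError(f"line {lineno}: expected tab-separated fields")
        rid = fields[0].strip()
        stoich, rev_from_arrow = parse_equation(fields[1], rid)
        rev_flag = bool(int(fields[2])) if len(fields) > 2 and fields[2].strip() else False
        genes = tuple(
            g.strip() for g in fields[3].split(",") if g.strip()
        ) if len(fields) > 3 else ()
        reactions.append(
            Reaction(rid, stoich, reversible=rev_from_arrow or rev_flag, genes=genes)
        )
    if not reactions:
        raise ModelError("model file defines no reactions")
    if substrate is None or product is None or biomass is None:
        raise ConfigError(
            "model file must declare #substrate, #product and #biomass reactions"
        )
    met_ids: list[str] = []
    seen = set()
    for r in reactions:
        for m in r.stoichiometry:
            if m not in seen:
                seen.add(m)
                met_ids.append(m)
    metabolites = [
        Metabolite(m, is_internal=not m.endswith(EXTERNAL_SUFFIX)) for m in met_ids
    ]
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        substrate_rxn=substrate,
        product_rxn=product,
        biomass_rxn=biomass,
        mw=mw,
        name=name,
    )


def dumps_model(model: StoichiometricModel) -> str:
    lines = [
        f"#substrate\t{model.substrate_rxn}",
        f"#product\t{model.product_rxn}",
        f"#biomass\t{model.biomass_rxn}",
    ]
    for species, weight in sorted(model.mw.items()):
        lines.append(f"#mw\t{species}\t{weight:g}")
    for r in model.reactions:
        genes = ",".join(r.genes)
        lines.append(f"{r.id}\t{format_equation(r)}\t{int(r.reversible)}\t{genes}")
    return "\n".join(lines) + "\n"


def load_model(path, format: str = "tsv", name: str | None = None) -> StoichiometricModel:
    """Load a model file in the TSV dialect or (optionally) SBML level 3.

    SBML reading is delegated to :mod:`cobra` when installed; only
    stoichiometry and reversibility are taken from SBML, and the designated
    reactions must then be set on the returned object by the caller.
    """
    path = str(path)
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            return loads_model(fh.read(), name=name if name is not None else path)
    if format == "sbml":
        return _load_sbml(path, name=name)
    raise ValueError(f"unknown model format {format!r}")


def _load_sbml(path: str, name: str | None) -> StoichiometricModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("SBML support requires the 'cobra' package") from exc
    cm = cobra.io.read_sbml_model(path)
    metabolites = [
        Metabolite(m.id, name=m.name or "", is_internal=not m.id.endswith(EXTERNAL_SUFFIX))
        for m in cm.metabolites
    ]
    reactions = []
    exchange_ids = {r.id for r in cm.exchanges}
    for r in cm.reactions:
        if r.id in exchange_ids:
            continue
        stoich = {m.id: _as_fraction(c) for m, c in r.metabolites.items()}
        reactions.append(Reaction(r.id, stoich, reversible=r.reversibility))
    first = reactions[0].id
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        substrate_rxn=first,
        product_rxn=first,
        biomass_rxn=first,
        name=name or cm.id or path,
    )


def save_model(model: StoichiometricModel, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write(dumps_model(model))


# ---------------------------------------------------------------------------
# Built-in toy fixtures
# ---------------------------------------------------------------------------

MW_GLUCOSE = 180.156
MW_ETHANOL = 46.069


def _toy_branch() -> StoichiometricModel:
    """TOY-BRANCH: one internal metabolite, three irreversible reactions.

    UPT: S_ext -> A;  PRD: A -> P_ext;  BYP: A -> B_ext.

    Complete EM set (2 modes): {UPT, PRD} and {UPT, BYP}, each with unit
    coefficients.  PRD is the designated product reaction and BYP doubles as
    the biomass reaction, so exactly one mode produces product and one
    produces biomass.
    """
    reactions = [
        Reaction("UPT", {"S_ext": Fraction(-1), "A": Fraction(1)}),
        Reaction("PRD", {"A": Fraction(-1), "P_ext": Fraction(1)}),
        Reaction("BYP", {"A": Fraction(-1), "B_ext": Fraction(1)}),
    ]
    mets = [
        Metabolite("S_ext", is_internal=False),
        Metabolite("A"),
        Metabolite("P_ext", is_internal=False),
        Metabolite("B_ext", is_internal=False),
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        substrate_rxn="UPT",
        product_rxn="PRD",
        biomass_rxn="BYP",
        mw={"substrate": 100.0, "product": 50.0},
        name="TOY-BRANCH",
    )


def _toy_rev() -> StoichiometricModel:
    """TOY-REV: linear chain with one reversible interconversion.

    UPT: S_ext -> A;  ISO: A <-> B;  OUT: B -> P_ext.

    After splitting ISO into forward/backward directions the split network has
    two elementary vectors: the through-path {UPT, ISO+, OUT} and the spurious
    2-cycle {ISO+, ISO-}.  The 2-cycle is excluded, so the genuine EM set has
    exactly 1 mode.
    """
    reactions = [
        Reaction("UPT", {"S_ext": Fraction(-1), "A": Fraction(1)}),
        Reaction("ISO", {"A": Fraction(-1), "B": Fraction(1)}, reversible=True),
        Reaction("OUT", {"B": Fraction(-1), "P_ext": Fraction(1)}),
    ]
    mets = [
        Metabolite("S_ext", is_internal=False),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("P_ext", is_internal=False),
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        substrate_rxn="UPT",
        product_rxn="OUT",
        biomass_rxn="OUT",
        mw={"substrate": 100.0, "product": 100.0},
        name="TOY-REV",
    )


def _toy_coupled() -> StoichiometricModel:
    """TOY-COUPLED: a 10-reaction core-metabolism caricature.

    Glycolysis-like backbone with an ethanologenic product route, a biomass
    route drawing on G6P and OAA, two fermentative byproduct drains, and a
    reversible pyruvate exchange:

      UPT:  GLC_ext -> G6P                (glucose uptake, substrate)
      EMP:  G6P -> 2 PYR                  (lumped glycolysis)
      PDC:  PYR -> ACA + CO2_ext          (decarboxylation)
      ADH:  ACA -> ETH_ext                (ethanol formation, product)
      LDH:  PYR -> LAC_ext                (lactate drain)
      PTA:  ACA -> ACE_ext                (acetate drain)
      PPC:  PYR -> OAA                    (anaplerosis)
      BIO:  G6P + 2 OAA -> BIO_ext        (biomass, biomass reaction)
      PYX:  PYR <-> PYR_ext               (reversible pyruvate exchange)
      MAL:  OAA -> MAL_ext                (malate drain)

    The homoethanologenic route UPT+EMP+2·PDC+2·ADH converts one glucose to
    two ethanol and two CO2, so the maximal product mass yield is
    2·46.069/180.156 = 0.511 g/g.  The complete EM set has 11 modes (verified
    by brute force over supports): six glucose-fed routes (ethanol, acetate,
    lactate, pyruvate export, malate, biomass), four pyruvate-fed routes
    through the reverse exchange, and one mixed glucose+pyruvate biomass
    mode.  Deleting the drain reactions (LDH, PTA, PYX, MAL) strictly
    improves coupled product×biomass fitness, which the knockout-search tests
    exploit.
    """
    F = Fraction
    reactions = [
        Reaction("UPT", {"GLC_ext": F(-1), "G6P": F(1)}, genes=("ptsG",)),
        Reaction("EMP", {"G6P": F(-1), "PYR": F(2)}, genes=("pfkA", "pykF")),
        Reaction("PDC", {"PYR": F(-1), "ACA": F(1), "CO2_ext": F(1)}, genes=("pdc",)),
        Reaction("ADH", {"ACA": F(-1), "ETH_ext": F(1)}, genes=("adhB",)),
        Reaction("LDH", {"PYR": F(-1), "LAC_ext": F(1)}, genes=("ldhA",)),
        Reaction("PTA", {"ACA": F(-1), "ACE_ext": F(1)}, genes=("pta", "ackA")),
        Reaction("PPC", {"PYR": F(-1), "OAA": F(1)}, genes=("ppc",)),
        Reaction("BIO", {"G6P": F(-1), "OAA": F(-2), "BIO_ext": F(1)}, genes=("BIO",)),
        Reaction("PYX", {"PYR": F(-1), "PYR_ext": F(1)}, reversible=True, genes=("pyx",)),
        Reaction("MAL", {"OAA": F(-1), "MAL_ext": F(1)}, genes=("mdh",)),
    ]
    met_ids_internal = ["G6P", "PYR", "ACA", "OAA"]
    met_ids_external = [
        "GLC_ext", "CO2_ext", "ETH_ext", "LAC_ext", "ACE_ext",
        "BIO_ext", "PYR_ext", "MAL_ext",
    ]
    mets = [Metabolite(m) for m in met_ids_internal] + [
        Metabolite(m, is_internal=False) for m in met_ids_external
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        substrate_rxn="UPT",
        product_rxn="ADH",
        biomass_rxn="BIO",
        mw={"substrate": MW_GLUCOSE, "product": MW_ETHANOL},
        name="TOY-COUPLED",
    )


_FIXTURES = {
    "TOY-BRANCH": _toy_branch,
    "TOY-REV": _toy_rev,
    "TOY-COUPLED": _toy_coupled,
}


def toy_fixture(name: str) -> StoichiometricModel:
    """Return a built-in toy model by catalogue name.

    Catalogue: ``TOY-BRANCH``, ``TOY-REV``, ``TOY-COUPLED`` (see each
    builder's docstring for the documented EM set).
    """
    try:
        builder = _FIXTURES[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture_dgf_table(name: str) -> dict[str, float]:
    """Synthetic standard Gibbs energies of formation (kcal/mol) for a fixture.

    These are invented, physically plausible values for testing the
    thermodynamic pipeline; they are not measured or group-contribution data.
    Most routes come out exergonic; in TOY-COUPLED the forward pyruvate
    export is made endergonic so that exactly one mode (glucose → exported
    pyruvate) has ΔGp° > 0 and the infeasible-mode filter is exercised.
    """
    tables = {
        "TOY-BRANCH": {"S_ext": -100.0, "A": -105.0, "P_ext": -112.0, "B_ext": -109.0},
        "TOY-REV": {"S_ext": -100.0, "A": -104.0, "B": -103.0, "P_ext": -110.0},
        "TOY-COUPLED": {
            "GLC_ext": -219.2, "G6P": -218.0, "PYR": -113.4, "ACA": -33.4,
            "CO2_ext": -92.3, "ETH_ext": -43.4, "LAC_ext": -123.0,
            "ACE_ext": -88.3, "OAA": -190.5, "BIO_ext": -610.0,
            "PYR_ext": -105.0, "MAL_ext": -201.0,
        },
    }
    try:
        return dict(tables[name.upper()])
    except KeyError:
        raise KeyError(f"no ΔGf° table for fixture {name!r}") from None


def random_toy_model(
    rng: np.random.Generator,
    n_internal: int = 3,
    n_reactions: int = 8,
    p_reversible: float = 0.25,
) -> StoichiometricModel:
    """Generate a random small network for property-based testing.

    Reactions connect a random uptake/chain/secretion structure over
    ``n_internal`` internal metabolites, with integer coefficients in {1, 2}
    and each reaction reversible with probability ``p_reversible``.  Designed
    so every network parses and validates; the EM set may be empty.
    """
    internal = [f"M{i}" for i in range(n_internal)]
    externals = ["X_in", "X_out"]
    reactions: list[Reaction] = []
    # guarantee one uptake and one secretion so closed pathways can exist
    reactions.append(Reaction("R_up", {"X_in": Fraction(-1), internal[0]: Fraction(1)}))
    reactions.append(
        Reaction("R_sec", {internal[-1]: Fraction(-1), "X_out": Fraction(1)})
    )
    for k in range(n_reactions - 2):
        a, b = rng.choice(n_internal, size=2, replace=False)
        ca = int(rng.integers(1, 3))
        cb = int(rng.integers(1, 3))
        stoich = {internal[a]: Fraction(-ca), internal[b]: Fraction(cb)}
        if rng.random() < 0.2:  # occasionally secrete a byproduct too
            stoich["X_out"] = Fraction(1)
        reactions.append(
            Reaction(f"R{k}", stoich, reversible=bool(rng.random() < p_reversible))
        )
    mets = [Metabolite(m) for m in internal] + [
        Metabolite(m, is_internal=False) for m in externals
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        substrate_rxn="R_up",
        product_rxn="R_sec",
        biomass_rxn="R_sec",
        mw={"substrate": 100.0, "product": 100.0},
        name="RANDOM-TOY",
    )
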