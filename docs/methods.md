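# Methods

## Model representation

A stoichiometric model partitions species into internal metabolites
(balanced at steady state; one row of `S` each) and external
sources/sinks (suffix `_ext` in the TSV dialect; never constrain the
nullspace). Three reactions are designated explicitly in the file header —
substrate uptake, product formation, biomass — rather than inferred,
because these roles are model-specific. Stoichiometric coefficients are
stored as exact rationals (`fractions.Fraction`; floats are converted with
denominator limit 10⁶) so that rank decisions in the elementarity tests are
exact rather than tolerance-based. The loader does not require protons or
water to be balanced; any consistent convention in the input file is
accepted as-is. A product species need not be mass-balanced in its
formation reaction (heterologous products are often written as unbalanced
sinks); the product flux is always read from the designated product
reaction.

Molecular weights enter only through mass yields and are supplied under the
role keys `substrate` and `product` (g/mol).

## Elementary-mode enumeration

Reversible reactions are split into forward/backward irreversible columns,
making the flux cone `{v ≥ 0 : S v = 0}` pointed. Enumeration is the
classical double-description tableau: candidates start as the unit rays,
and each internal metabolite constraint keeps the zero-residual candidates
plus all positive×negative combinations, pruning any candidate whose
support strictly contains another's. Combination coefficients and residuals
are rescaled jointly to coprime integers to bound coefficient growth.
After the last constraint, spurious two-cycles (forward+backward of one
reversible reaction) are discarded, surviving rays are folded back to
signed coefficients over the original reactions, and duplicates are merged.
A mode whose support is entirely reversible is valid in both orientations
and is reported once, oriented so its substrate flux (or failing that its
first nonzero coefficient) is positive.

Normalization: substrate-consuming modes are scaled to unit substrate
uptake — this makes `v = M·c` a per-unit-glucose flux distribution and
makes pathway energies scale-consistent — and all other modes to
max|coefficient| = 1.

Completeness is not taken on faith: `brute_force_efms` independently
enumerates candidate supports (guarded at 18 split reactions), keeping a
support iff the restricted rational nullspace is one-dimensional with a
sign-feasible, fully-supported generator and no kept support is a proper
subset. The test suite requires support-set equality between the two
enumerators on every fixture and on randomized networks, plus per-mode
checks of `S·e = 0` (exact), sign feasibility, and the rank criterion
`rank(S|support) = |support| − 1`.

The tableau algorithm is exponential in the worst case and is intended for
the small (≲ 60–70 reaction) central-metabolism models this kind of
analysis targets; no out-of-core or parallel guarantees are made.

## Pathway thermodynamics and weighting

`ΔG°_r` is either supplied per reaction or derived as `Σ ν_i ΔG°_f,i`;
currency metabolites omitted from the balanced matrix can be restored for
the energy bookkeeping via a per-reaction `extra_stoich` map. The pathway
energy of a mode is `ΔG°_p = Σ_j e_j ΔG°_r,j` with signed coefficients, so
a reversible reaction used backward contributes `−ΔG°_r`. Because modes
are normalized to unit substrate uptake, `ΔG°_p` is well-defined per unit
substrate; modes without substrate uptake keep their computed `ΔG°_p` and
participate in weighting, but contribute zero to yields.

The thermodynamic weighting uses the Boltzmann form
`c_i ∝ exp(−ΔG°_p,i / RT)` for feasible modes (`ΔG°_p ≤ 0`), zero for
infeasible ones, normalized to `Σc = 1`. The exponential is the canonical
choice for a log-linear relationship between weight and pathway free
energy; it is isolated behind a single policy function
(`thermo.boltzmann_policy`) so an alternative monotone law can be swapped
without touching callers. Exponents are shifted by their maximum before
exponentiation; the shift cancels in normalization, so strongly exergonic
pathways cannot overflow. At physiological temperature `RT ≈ 0.62
kcal/mol`, so pathway-energy differences of a few kcal/mol concentrate
essentially all weight on the most exergonic surviving mode — equal
weighting is therefore the conservative reference scheme, and the two are
reported side by side. If every surviving mode is infeasible the zero
vector is returned with a flag and strain fitness is 0. Equal weighting
applies no feasibility filter.

Default temperature 310.15 K; `R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`. No
activity/concentration corrections (ΔG vs ΔG°) are attempted.

## FBA

`fba_fluxes` maximizes one reaction's flux subject to `S·v = 0`, substrate
uptake fixed to 1, and capacity bounds `[−10, 10]` (reversible) / `[0, 10]`
(irreversible), solved with HiGHS via `scipy.optimize.linprog`. With
uptake fixed and capacity bounds non-binding, the optimum lies on an
extreme ray, so the LP objective per unit substrate must equal the best
per-substrate yield over the EM set — an invariant the tests check on every
fixture. Alternate optima are possible; one solver vertex is reported and
reaction-wise comparisons with EM-weighted fluxes carry that caveat.
Infeasible programs raise rather than return zeros.

## Knockout search

**Genotype.** One bit per deletable reaction (1 = present). Reactions whose
single removal drives the maximal product *or* biomass yield to zero are
protected (always 1): they could only produce dead strains, and excluding
them shrinks the search space. The screen reuses the knockout-subset
property — the EM set of a deletion strain is exactly the parent modes
whose supports avoid the deleted reactions — which the test suite verifies
against direct re-enumeration of the submodel; per-strain re-enumeration is
retained as a debug path (`StrainEvaluator(reenumerate=True)`).

**Fitness.** Strain yields are the weight-vector average of per-mode
yields, divided by the *parent* model's theoretical yields so all fitness
values are comparable fractions in [0, 1]; the coupled objective is their
product, which is zero whenever either product or biomass formation is
lost. Fractions are clipped to [0, 1] to guard against modes driving a
reversible product reaction backward. Degenerate strains (no surviving
modes, all modes infeasible) score 0.

**GA.** Elitist generational GA: population 50 with 5 elites by default,
two-point crossover (fraction 0.8), uniform per-bit mutation (rate 0.01),
tournament (size 2) or roulette selection, initial individuals seeded with
2–6 knockouts (random dense seeding mostly produces dead strains).
Mutation and crossover parameters are deliberately plain and configurable;
they were not tuned. Termination: relative best-fitness change below 10⁻⁶
over 25 consecutive generations, or 100 generations. Elites pass unchanged,
so the best fitness is non-decreasing — a tested invariant. Evaluations are
cached by chromosome, and identical seeds reproduce identical histories.

**Exhaustive oracle.** All knockout combinations up to a budget
(≤ 10⁶ combinations) are evaluated with deterministic lexicographic
tie-breaking; on fixtures the GA must reach the oracle optimum for 10/10
seeds. Because the GA is stochastic, fixture-level claims are stated as
best-of-seeds, never single-run equality.

**MOGA.** NSGA-II machinery (fast non-dominated sort, crowding distance,
binary tournament on rank then crowding) with controlled elitism: front-1
survivors are capped at a Pareto fraction (default 0.35) of the population
(default 200) when later fronts still have candidates. There is no natural
stall criterion for a front, so termination is a generation cap (default
200), recorded in the result metadata. The returned front is re-verified
against a brute-force dominance filter; the per-generation hypervolume
(reference (0,0)) is non-decreasing whenever the cap is not binding, which
is the regime the fixture tests run in.

## Fixtures and the synthetic-data surface

Three built-in networks carry the always-on tests:

* `TOY-BRANCH` — one internal metabolite, three irreversible reactions,
  exactly 2 EMs; the minimal classification/weighting example.
* `TOY-REV` — one reversible interconversion; its split network has a
  through-path and a spurious 2-cycle, pinning the 2-cycle exclusion.
* `TOY-COUPLED` — 10 reactions, 11 EMs (verified by brute force): a lumped
  glycolysis/fermentation caricature whose ethanologenic route reproduces
  the analytic 0.511 g/g ethanol-on-glucose limit with real molecular
  weights, and whose drain reactions give the knockout search a nontrivial,
  exhaustively-checkable optimum (protected backbone of 6 reactions, 4-bit
  genotype space, coupled optimum 0.125).

The fixture ΔGf° tables are synthetic: physically plausible magnitudes
chosen so most routes are exergonic and exactly one TOY-COUPLED mode
(pyruvate export) is infeasible, exercising the zero-weight path. They are
not measured or group-contribution values.

`random_toy_model` generates small random networks (guaranteed uptake and
secretion reactions, integer coefficients, optional reversibility) for
property-based oracle-equivalence testing. These toys emulate the
*structure* of central-metabolism models — branching, reversibility,
byproduct drains — but not their scale (tens of thousands of EMs), cofactor
coupling, or realistic energies; passing tests demonstrate algorithmic
correctness, not biological fidelity, and full-scale claims are tied to the
published case-study models, which must be supplied by the user (see
`data/models/README.md`).

Problem sizes used by the test suite and `scripts/acceptance.py` (50 and 25
random networks respectively, 10 GA seeds, populations 16–24, ≤ 40
generations) were chosen so the whole suite completes in seconds while
still covering every code path; all are configurable upward.

## Numerical choices and degenerate inputs

* Rational arithmetic end-to-end in enumeration; float conversion happens
  only at the yield/weighting boundary. "Produces X" means coefficient
  > 10⁻⁹ after normalization (exact positivity in the rational pipeline).
* Max-yield ties are collected within relative tolerance 10⁻⁶ and ordered
  by lexicographic support.
* A model with a single reaction touching an internal metabolite has no
  steady state and an empty EM set; empty EM sets yield zero weights and
  zero fitness throughout rather than errors.
* Deleting a designated reaction invalidates a model by construction;
  designated reactions are always essential, so the search never proposes
  this, and `apply_knockouts` surfaces it as a configuration error.

## Known limitations

* Enumeration is for small networks; genome-scale models are out of scope.
* One-to-one reaction↔gene association; no many-to-many gene-protein-
  reaction mapping, no insertion/over-expression moves.
* Standard-condition energies only; no metabolite-concentration
  corrections.
* SBML input (via cobra, optional) reads stoichiometry and reversibility
  only; designated roles must be set afterwards.
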