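# emdesign

Elementary-mode analysis, pathway thermodynamics, and genetic-algorithm
strain design for small stoichiometric metabolic models.

## The problem

Microbial production strains must divert carbon from growth toward a
product, yet stay viable. For a small metabolic network (tens of
reactions), every feasible steady-state flux distribution is a nonnegative
combination of the network's **elementary flux modes (EMs)** — the minimal,
non-decomposable pathways compatible with stoichiometry and reaction
irreversibility. `emdesign` uses this convex-analysis structure to (1)
reconstruct flux distributions without any optimality assumption about the
cell, and (2) search the space of reaction-knockout genotypes for strains
with high product yield, biomass yield, or both.

## The method

1. **EM enumeration.** Reversible reactions are split into irreversible
   direction pairs and the extreme rays of the flux cone
   `{v : S·v = 0, v ≥ 0}` are enumerated by the classical
   double-description tableau algorithm in exact rational arithmetic;
   spurious two-cycles are removed and modes folded back to signed
   coefficients. An independent brute-force oracle over candidate supports
   verifies completeness on small networks.
2. **Flux reconstruction.** The flux vector is `v = M·c`, where the columns
   of `M` are the EMs (normalized to unit substrate uptake) and `c` is a
   weight vector with `Σc = 1`. Weights are either *equal* (`c_i = 1/n`) or
   *thermodynamic*: `c_i ∝ exp(−ΔG°_p,i / RT)` with the pathway energy
   `ΔG°_p = Σ_j e_j ΔG°_r,j` summed over the mode's reactions
   (`R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`, `T = 310.15 K`). Modes with
   `ΔG°_p > 0` are thermodynamically infeasible and receive weight 0.
3. **FBA comparison.** A linear program maximizing biomass with substrate
   uptake fixed to 1 (bounds `[−10, 10]` / `[0, 10]`) provides the
   optimization-based flux estimate the EM weighting is compared against.
4. **Knockout search.** A strain is a binary chromosome over deletable
   reactions; modes of a deletion strain are exactly the parent modes whose
   supports avoid the deleted reactions. An elitist GA (population 50,
   5 elites, two-point crossover, uniform mutation, tournament or roulette
   selection, seeded with 2–6 knockouts) maximizes the product-yield
   fraction, the biomass-yield fraction, or their product — all expressed
   relative to the parent network's theoretical (best-EM) yields. A
   controlled-elitist NSGA-II variant returns the Pareto front of the two
   objectives instead of a scalar optimum. Reactions whose single removal
   abolishes all product or all biomass formation are pre-screened and
   protected.

## Worked example

The built-in `TOY-COUPLED` fixture is a 10-reaction caricature of glucose
fermentation: lumped glycolysis, an ethanologenic route (glucose → 2
ethanol + 2 CO₂), a biomass reaction drawing on G6P and oxaloacetate,
lactate/acetate/malate drains and a reversible pyruvate exchange.

```bash
emdesign enumerate --fixture TOY-COUPLED --out demo
```

```
  "n_total": 11,
  "n_product": 2,
  "n_biomass": 2,
  "max_product_yield": { "value": 0.5114345345145319, "n_modes_attaining": 1, ... },
  "n_infeasible": 1,
  "pct_infeasible": 9.09
```

The network supports 11 EMs; two form ethanol, two form biomass, and one
(pyruvate export) is thermodynamically infeasible under the fixture's ΔGf°
table. The maximal ethanol mass yield, 0.511 g/g, is exactly
2·MW(ethanol)/MW(glucose) — the homoethanologenic stoichiometric limit.

```bash
emdesign ga --fixture TOY-COUPLED --objective coupled --population 20 \
            --generations 40 --seed 1 --out demo-ga
```

```
  "best_fitness": 0.125,
  "n_protected": 6,
  "removed_reactions": ["LDH", "PTA", "PYX", "MAL"],
  "n_ems": 2,
  "product_yield_fraction": 0.5,
  "biomass_yield_fraction": 0.25
```

The essentiality screen protects the six backbone reactions, leaving a
4-bit genotype space; the GA deletes all four drain reactions, leaving only
the ethanol and biomass modes (coupled fitness 0.5 × 0.25 = 0.125, the
exhaustive-search optimum). `emdesign moga` returns the Pareto front of
(product fraction, biomass fraction) pairs instead, and `emdesign fba`
writes the LP flux distribution for side-by-side comparison.

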