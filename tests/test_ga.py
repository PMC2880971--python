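"""Knockout GA: essentiality screen, strain fitness, evolution, oracle."""

import numpy as np
import pytest

from emdesign import (
    GAConfig,
    StrainEvaluator,
    ThermoTable,
    enumerate_efms,
    essential_reactions,
    exhaustive_search,
    run_ga,
    toy_fixture,
)


class TestEssentiality:
    def test_toy_coupled_protected_set(self, toy_coupled, coupled_ems,
                                       coupled_protected):
        # backbone + anaplerosis + designated reactions are lethal singles;
        # the four drains (LDH, PTA, PYX, MAL) remain searchable
        assert coupled_protected == {"UPT", "EMP", "PDC", "ADH", "PPC", "BIO"}
        deletable = set(toy_coupled.reaction_ids) - coupled_protected
        assert deletable == {"LDH", "PTA", "PYX", "MAL"}

    def test_substrate_is_always_protected(self, toy_branch):
        assert "UPT" in essential_reactions(toy_branch)


class TestStrainEvaluation:
    def test_parent_strain_tradeoff(self, toy_coupled, coupled_ems,
                                    coupled_protected, small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        rec = ev.evaluate([1, 1, 1, 1])
        # wild-type averages over all modes: neither fraction reaches 1
        assert 0 < rec.product_fraction < 1
        assert 0 < rec.biomass_fraction < 1
        assert rec.coupled == pytest.approx(
            rec.product_fraction * rec.biomass_fraction)
        assert rec.n_modes == 11

    def test_equal_weighting_fractions_are_exact(self, toy_coupled, coupled_ems,
                                                 coupled_protected,
                                                 small_ga_config):
        """Wild-type equal weighting: 1 of 11 modes at max product yield,
        biomass modes at 0.5 and 1.0 of a 1.0 theoretical yield."""
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        rec = ev.evaluate([1, 1, 1, 1])
        assert rec.product_fraction == pytest.approx(1 / 11)
        assert rec.biomass_fraction == pytest.approx(1.5 / 11)

    def test_drain_deletions_reach_isolated_optimum(self, toy_coupled,
                                                    coupled_ems,
                                                    coupled_protected,
                                                    small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        rec = ev.evaluate([0, 0, 0, 0])  # delete LDH, PTA, PYX, MAL
        assert rec.n_modes == 2  # ethanol mode + biomass mode survive
        assert rec.product_fraction == pytest.approx(0.5)
        assert rec.biomass_fraction == pytest.approx(0.25)
        assert rec.coupled == pytest.approx(0.125)

    def test_fitness_bounds_over_all_genotypes(self, toy_coupled, coupled_ems,
                                               coupled_protected,
                                               small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        for g in range(2 ** ev.n_bits):
            bits = [(g >> k) & 1 for k in range(ev.n_bits)]
            rec = ev.evaluate(bits)
            assert 0.0 <= rec.product_fraction <= 1.0
            assert 0.0 <= rec.biomass_fraction <= 1.0
            assert rec.coupled <= min(rec.product_fraction, rec.biomass_fraction)

    def test_filtering_equals_reenumeration(self, toy_coupled, coupled_ems,
                                            coupled_protected, small_ga_config):
        fast = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                               protected=coupled_protected)
        slow = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                               protected=coupled_protected, reenumerate=True)
        for bits in ([1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 1]):
            a, b = fast.evaluate(bits), slow.evaluate(bits)
            assert a.product_fraction == pytest.approx(b.product_fraction)
            assert a.biomass_fraction == pytest.approx(b.biomass_fraction)
            assert a.n_modes == b.n_modes

    def test_thermodynamic_weighting_changes_fitness(self, toy_coupled,
                                                     coupled_ems,
                                                     coupled_protected,
                                                     coupled_table):
        cfg_eq = GAConfig(weighting_scheme="equal")
        cfg_th = GAConfig(weighting_scheme="thermodynamic")
        ev_eq = StrainEvaluator(toy_coupled, cfg_eq, parent_ems=coupled_ems,
                                protected=coupled_protected)
        ev_th = StrainEvaluator(toy_coupled, cfg_th, coupled_table,
                                parent_ems=coupled_ems,
                                protected=coupled_protected)
        wt_eq = ev_eq.evaluate([1, 1, 1, 1])
        wt_th = ev_th.evaluate([1, 1, 1, 1])
        assert wt_eq.coupled != pytest.approx(wt_th.coupled)

    def test_thermo_weighting_requires_table(self, toy_coupled):
        with pytest.raises(ValueError, match="ThermoTable"):
            StrainEvaluator(toy_coupled, GAConfig(weighting_scheme="thermodynamic"))


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(elite_count=50),
        dict(mutation_rate=1.5),
        dict(initial_knockouts_range=(4, 2)),
        dict(fitness="nope"),
        dict(weighting_scheme="nope"),
        dict(selection="nope"),
        dict(max_generations=0),
    ])
    def test_inconsistent_config_rejected(self, bad):
        cfg = GAConfig(**bad)
        with pytest.raises(ValueError):
            cfg.validate()


class TestExhaustive:
    def test_zero_knockouts_returns_parent(self, toy_coupled, coupled_ems,
                                           coupled_protected, small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        best = exhaustive_search(toy_coupled, 0, small_ga_config, evaluator=ev)
        assert best.bits == (1, 1, 1, 1)

    def test_best_pair_for_coupled_fitness(self, toy_coupled, coupled_ems,
                                           coupled_protected, small_ga_config):
        """With ≤2 deletions the optimum removes the pyruvate exchange plus
        one other drain (three tying pairs at coupled fitness 1/32)."""
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        best = exhaustive_search(toy_coupled, 2, small_ga_config, evaluator=ev)
        assert best.fitness == pytest.approx(1 / 32)
        assert "PYX" in ev.removed_reactions(best.bits)
        assert best.n_removals == 2

    def test_monotone_in_knockout_budget(self, toy_coupled, coupled_ems,
                                         coupled_protected, small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        fits = [exhaustive_search(toy_coupled, k, small_ga_config,
                                  evaluator=ev).fitness for k in range(5)]
        assert fits == sorted(fits)
        assert fits[-1] == pytest.approx(0.125)

    def test_budget_guard(self, toy_coupled, monkeypatch):
        import emdesign.ga as ga_mod

        monkeypatch.setattr(ga_mod, "_EXHAUSTIVE_BUDGET", 2)
        with pytest.raises(ValueError, match="budget"):
            exhaustive_search(toy_coupled, 4, GAConfig())


class TestGA:
    def test_elitism_makes_best_monotone(self, toy_coupled, coupled_ems,
                                         coupled_protected, small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        res = run_ga(toy_coupled, small_ga_config, evaluator=ev)
        best_series = [h["best"] for h in res.history]
        assert best_series == sorted(best_series)

    def test_identical_seed_identical_history(self, toy_coupled, coupled_ems,
                                              coupled_protected):
        runs = []
        for _ in range(2):
            cfg = GAConfig(population_size=16, elite_count=2,
                           max_generations=15, rng_seed=7)
            ev = StrainEvaluator(toy_coupled, cfg, parent_ems=coupled_ems,
                                 protected=coupled_protected)
            runs.append(run_ga(toy_coupled, cfg, evaluator=ev))
        assert runs[0].history == runs[1].history
        assert runs[0].best.bits == runs[1].best.bits

    @pytest.mark.parametrize("seed", range(10))
    def test_ga_reaches_exhaustive_optimum(self, seed, toy_coupled, coupled_ems,
                                           coupled_protected):
        """10/10 seeded runs match the exhaustive coupled-fitness optimum."""
        cfg = GAConfig(population_size=20, elite_count=3, max_generations=40,
                       rng_seed=seed, initial_knockouts_range=(1, 3))
        ev = StrainEvaluator(toy_coupled, cfg, parent_ems=coupled_ems,
                             protected=coupled_protected)
        oracle = exhaustive_search(toy_coupled, 4, cfg, evaluator=ev)
        res = run_ga(toy_coupled, cfg, evaluator=ev)
        assert res.best.fitness == pytest.approx(oracle.fitness)

    def test_elitism_retains_seeded_optimum_without_variation(
            self, toy_coupled, coupled_ems, coupled_protected):
        cfg = GAConfig(population_size=8, elite_count=2, max_generations=5,
                       mutation_rate=0.0, crossover_fraction=0.0, rng_seed=3,
                       initial_knockouts_range=(4, 4))
        ev = StrainEvaluator(toy_coupled, cfg, parent_ems=coupled_ems,
                             protected=coupled_protected)
        # every individual is the all-drains-removed optimum; nothing to find
        res = run_ga(toy_coupled, cfg, evaluator=ev)
        assert res.best.fitness == pytest.approx(0.125)
        assert all(h["best"] == pytest.approx(0.125) for h in res.history)

    def test_roulette_selection_also_converges(self, toy_coupled, coupled_ems,
                                               coupled_protected):
        cfg = GAConfig(population_size=20, elite_count=3, max_generations=40,
                       rng_seed=5, selection="roulette")
        ev = StrainEvaluator(toy_coupled, cfg, parent_ems=coupled_ems,
                             protected=coupled_protected)
        res = run_ga(toy_coupled, cfg, evaluator=ev)
        assert res.best.fitness == pytest.approx(0.125)

    def test_product_objective_isolates_ethanol_route(self, toy_coupled,
                                                      coupled_ems,
                                                      coupled_protected):
        cfg = GAConfig(population_size=20, elite_count=3, max_generations=40,
                       rng_seed=11, fitness="product")
        ev = StrainEvaluator(toy_coupled, cfg, parent_ems=coupled_ems,
                             protected=coupled_protected)
        res = run_ga(toy_coupled, cfg, evaluator=ev)
        # removing every drain leaves ethanol + biomass modes: product 0.5;
        # the exhaustive optimum over this genotype space
        oracle = exhaustive_search(toy_coupled, 4, cfg, evaluator=ev)
        assert res.best.fitness == pytest.approx(oracle.fitness)

    def test_cache_avoids_reevaluation(self, toy_coupled, coupled_ems,
                                       coupled_protected, small_ga_config):
        ev = StrainEvaluator(toy_coupled, small_ga_config, parent_ems=coupled_ems,
                             protected=coupled_protected)
        run_ga(toy_coupled, small_ga_config, evaluator=ev)
        # only 16 distinct genotypes exist
        assert ev.n_evaluations <= 16
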