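import dataclasses

import numpy as np
import pandas as pd
import pytest

import evoface as ef
from evoface.ga_engine import session_from_json, session_to_json


def ideal_observer(target):
    return ef.ObserverModel(target=target, decision_noise_sd=0.0)


class TestInitPopulation:
    def test_population_count_and_validity(self, rng):
        gen = ef.init_population(ef.GAConfig(), rng)
        assert gen.index == 0
        assert gen.candidates.shape == (10, ef.N_CORE)
        assert gen.selected is None
        assert np.all((gen.candidates >= 0) & (gen.candidates <= 1))

    def test_deterministic_under_seed(self):
        a = ef.init_population(ef.GAConfig(), np.random.default_rng(3))
        b = ef.init_population(ef.GAConfig(), np.random.default_rng(3))
        assert np.array_equal(a.candidates, b.candidates)

    def test_mean_activation_matches_generator_law(self):
        # activated fraction * mean magnitude = activation_prob * 1/2 (uniform)
        cfg = ef.GAConfig(activation_prob=0.3)
        rng = np.random.default_rng(11)
        total = np.mean(
            [ef.init_population(cfg, rng).candidates.mean() for _ in range(1000)]
        )
        expect = 0.3 * 0.5
        # 3 SE of the per-weight mean over 1000*10*46 draws
        se = np.sqrt(0.25 / (1000 * 10 * ef.N_CORE))
        assert abs(total - expect) < 3 * se + 1e-3


class TestNextGeneration:
    def test_no_variation_operators_copy_parent(self, rng):
        cfg = ef.GAConfig(mutation_prob=0.0, elitism=True)
        gen = ef.init_population(cfg, rng)
        gen = dataclasses.replace(gen, selected=[4], best_index=4)
        child = ef.next_generation(gen, cfg, rng)
        assert np.all(child.candidates == gen.candidates[4])

    def test_elitism_preserves_best(self, rng):
        cfg = ef.GAConfig()
        gen = ef.init_population(cfg, rng)
        gen = dataclasses.replace(gen, selected=[1, 5, 7], best_index=5)
        child = ef.next_generation(gen, cfg, rng)
        assert np.array_equal(child.candidates[0], gen.candidates[5])

    def test_empty_selection_rejected(self, rng):
        cfg = ef.GAConfig()
        gen = ef.init_population(cfg, rng)
        with pytest.raises(ValueError, match="select at least one"):
            ef.next_generation(gen, cfg, rng)

    def test_offspring_stay_in_bounds(self, rng):
        cfg = ef.GAConfig(mutation_prob=1.0, mutation_sd=5.0, mutation_decay=1.0)
        gen = ef.init_population(cfg, rng)
        gen = dataclasses.replace(gen, selected=[0, 1], best_index=0)
        child = ef.next_generation(gen, cfg, rng)
        assert np.all((child.candidates >= 0) & (child.candidates <= 1))

    def test_mutation_matches_clipped_gaussian_oracle(self):
        # single parent at 0.5, always-mutate: offspring weights should match
        # clip(0.5 + N(0, sd)) in mean and sd
        sd = 0.2
        cfg = ef.GAConfig(
            mutation_prob=1.0, mutation_sd=sd, mutation_decay=1.0, elitism=False
        )
        parent = np.full(ef.N_CORE, 0.5)
        gen = ef.Generation(index=0, candidates=np.stack([parent] * 10),
                            selected=[0], best_index=0)
        rng = np.random.default_rng(5)
        draws = np.concatenate(
            [ef.next_generation(gen, cfg, rng).candidates.ravel() for _ in range(200)]
        )
        oracle = np.clip(
            0.5 + np.random.default_rng(99).normal(0, sd, size=draws.size), 0, 1
        )
        assert draws.mean() == pytest.approx(oracle.mean(), abs=3 * sd / np.sqrt(draws.size) + 1e-3)
        assert draws.std() == pytest.approx(oracle.std(), rel=0.02)


class TestRunSession:
    def test_generation_count(self, category_means):
        cfg = ef.GAConfig(n_generations=1)
        session = ef.run_session(
            ideal_observer(category_means["happy"]), cfg, np.random.default_rng(0)
        )
        assert len(session.generations) == 2

    def test_default_session_has_eleven_trials(self, category_means):
        session = ef.run_session(
            ideal_observer(category_means["sad"]), ef.GAConfig(), np.random.default_rng(0)
        )
        assert len(session.generations) == 11

    def test_preferred_is_final_choice(self, category_means):
        session = ef.run_session(
            ideal_observer(category_means["fear"]), ef.GAConfig(), np.random.default_rng(1)
        )
        final = session.generations[-1]
        assert final.selected == [final.best_index]
        assert np.array_equal(session.preferred, final.candidates[final.best_index])

    def test_reproducible_under_seed(self, category_means):
        obs = ef.ObserverModel(target=category_means["angry"])
        a = ef.run_session(obs, ef.GAConfig(), np.random.default_rng(42))
        b = ef.run_session(obs, ef.GAConfig(), np.random.default_rng(42))
        assert session_to_json(a) == session_to_json(b)

    def test_frozen_genotypes_without_variation(self, category_means):
        # no mutation: every offspring weight is copied verbatim from a
        # selected parent, and the elite carries over bitwise
        cfg = ef.GAConfig(mutation_prob=0.0, mutation_sd=0.0)
        obs = ideal_observer(category_means["happy"])
        session = ef.run_session(obs, cfg, np.random.default_rng(2))
        for prev, gen in zip(session.generations, session.generations[1:]):
            parents = prev.candidates[np.asarray(prev.selected)]
            assert np.array_equal(gen.candidates[0], prev.candidates[prev.best_index])
            for child in gen.candidates:
                assert np.all(np.isin(child, parents))

    def test_all_candidates_valid_everywhere(self, category_means):
        session = ef.run_session(
            ideal_observer(category_means["sad"]), ef.GAConfig(), np.random.default_rng(3)
        )
        for gen in session.generations:
            assert np.all((gen.candidates >= 0) & (gen.candidates <= 1))


class TestConvergenceProfile:
    def test_identical_generations_plateau_at_zero(self):
        cand = np.tile(np.linspace(0.1, 1, ef.N_CORE), (10, 1))
        gens = [
            ef.Generation(index=i, candidates=cand, selected=[0, 1, 2], best_index=0)
            for i in range(5)
        ]
        session = ef.GASession(config=ef.GAConfig(), generations=gens, preferred=cand[0])
        profile = ef.convergence_profile(session)
        assert np.all(profile["selected_dispersion"] == 0.0)
        assert ef.plateau_generation(profile) == 0

    def test_shrinking_then_flat_plateaus_at_first_flat_index(self):
        profile = pd.DataFrame(
            {
                "selected_dispersion": [0.6, 0.4, 0.2, 0.1, 0.1, 0.1],
                "single_selection": [False] * 6,
            }
        )
        # changes relative to scale 0.6: .33, .33, .17, 0, 0 -> flat from g=3
        assert ef.plateau_generation(profile) == 3

    def test_single_selection_flagged_and_zero(self, category_means):
        session = ef.run_session(
            ideal_observer(category_means["happy"]), ef.GAConfig(), np.random.default_rng(4)
        )
        profile = ef.convergence_profile(session, target=category_means["happy"])
        last = profile.iloc[-1]
        assert bool(last["single_selection"]) and last["selected_dispersion"] == 0.0
        assert "mean_cd_to_target" in profile.columns

    def test_plateau_rule_matches_independent_reimplementation(self, category_means):
        def oracle_plateau(d, tol=0.05):
            d = np.asarray(d, dtype=float)
            scale = max(d.max(), 1e-300)
            rel = np.abs(np.diff(d)) / scale
            for g in range(len(d)):
                if np.all(rel[g:] < tol):
                    return g
            return len(d) - 1

        obs = ef.ObserverModel(target=category_means["fear"])
        medians, oracle_medians = [], []
        for i in range(100):
            session = ef.run_session(obs, ef.GAConfig(), np.random.default_rng(500 + i))
            profile = ef.convergence_profile(session)
            kept = profile[~profile["single_selection"]]
            medians.append(ef.plateau_generation(profile))
            oracle_medians.append(oracle_plateau(kept["selected_dispersion"]))
        assert medians == oracle_medians


class TestSessionLog:
    def test_json_round_trip(self, category_means):
        session = ef.run_session(
            ideal_observer(category_means["angry"]), ef.GAConfig(seed=9),
            np.random.default_rng(9),
        )
        restored = session_from_json(session_to_json(session))
        assert session_to_json(restored) == session_to_json(session)
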