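"""Synthetic populations and Bernoulli choice simulation."""

import numpy as np
import pytest

import mixedgambles as mg
from mixedgambles.errors import InvalidInputError

from conftest import by_label


class TestSamplePopulation:
    def test_point_mass_hyperparams(self):
        spec = mg.PopulationSpec(
            n_agents=1, generator="cpt", seed=4,
            hyperparams={"lam_log_sd": 0.0, "bias_sd": 0.0},
        )
        (agent,) = mg.sample_population(spec)
        assert agent.params.lam == pytest.approx(2.0)
        assert agent.params.bias == pytest.approx(0.0)
        assert agent.params.mu == 1.0 and agent.params.alpha == 0.9

    def test_seeded_reproducibility(self):
        spec = mg.PopulationSpec(n_agents=8, generator="dbs", seed=13)
        assert mg.sample_population(spec) == mg.sample_population(spec)

    def test_lambda_sampler_median(self):
        spec = mg.PopulationSpec(n_agents=10_000, generator="cpt", seed=5)
        lams = [a.params.lam for a in mg.sample_population(spec)]
        assert 1.9 <= np.median(lams) <= 2.1

    def test_stable_ordered_ids(self):
        pop = mg.sample_population(mg.PopulationSpec(n_agents=3, generator="dbs", seed=0))
        assert [a.agent_id for a in pop] == ["a000", "a001", "a002"]

    def test_invalid_specs(self):
        with pytest.raises(InvalidInputError):
            mg.PopulationSpec(n_agents=0, generator="cpt")
        with pytest.raises(InvalidInputError):
            mg.PopulationSpec(n_agents=5, generator="magic")
        with pytest.raises(InvalidInputError):
            mg.PopulationSpec(n_agents=5, generator="cpt", hyperparams={"nope": 1.0})


class TestSimulateChoices:
    def test_degenerate_acceptor(self, small_conditions):
        agent = mg.CPTAgent("a1", mg.CPTParams(mu=0.0, bias=30.0))
        recs = mg.simulate_choices(agent, by_label(small_conditions, "LL"), n_reps=3, seed=1)
        assert recs["accepted"].all()
        assert len(recs) == 3 * 64

    def test_seeded_determinism(self, small_conditions):
        agent = mg.DbSAgent("a1", mg.DbSParams())
        cond = by_label(small_conditions, "HL")
        r1 = mg.simulate_choices(agent, cond, n_reps=2, seed=42)
        r2 = mg.simulate_choices(agent, cond, n_reps=2, seed=42)
        assert r1.equals(r2)

    def test_empirical_rate_matches_model_probability(self):
        cond = mg.build_condition(20, 20, 2, "T")  # 4 gambles
        agent = mg.CPTAgent("a1", mg.CPTParams(alpha=0.9, beta=0.9, lam=2.0, mu=0.3))
        n_reps = 25_000
        recs = mg.simulate_choices(agent, cond, n_reps=n_reps, seed=8)
        probs = agent.accept_probabilities(cond)
        rates = recs.groupby(["gain", "loss"], sort=False)["accepted"].mean()
        for g, p in zip(cond.gambles, probs):
            rate = rates[(g.gain, g.loss)]
            se = np.sqrt(p * (1 - p) / n_reps)
            assert abs(rate - p) < 3 * se

    def test_min_reps(self, small_conditions):
        cond = by_label(small_conditions, "LL")  # 64 gambles
        assert mg.min_reps(cond, 256) == 4
        assert mg.min_reps(cond, 64) == 1


class TestSimulateExperiment:
    def test_between_assignment_covers_conditions(self, small_conditions):
        pop = mg.sample_population(mg.PopulationSpec(n_agents=8, generator="dbs", seed=2))
        recs = mg.simulate_experiment(pop, small_conditions, n_reps=1, seed=2)
        per_agent = recs.groupby("agent_id")["condition"].nunique()
        assert (per_agent == 1).all()
        assert set(recs["condition"]) == {"LL", "LH", "HL", "HH"}

    def test_default_reps_reach_256_trials(self, small_conditions):
        pop = mg.sample_population(mg.PopulationSpec(n_agents=4, generator="dbs", seed=2))
        recs = mg.simulate_experiment(pop, small_conditions, seed=2)
        assert (recs.groupby("agent_id").size() >= 256).all()

    def test_pooled_dbs_choices_match_rank_predictions(self, small_conditions):
        """Large simulated populations reproduce the closed-form proportion table."""
        common = mg.common_gambles(small_conditions)
        spec = mg.PopulationSpec(
            n_agents=40, generator="dbs", seed=6, hyperparams={"sensitivity_sd": 0.0}
        )
        pop = mg.sample_population(spec)
        recs = mg.simulate_experiment(pop, small_conditions, n_reps=4, seed=6)
        observed = mg.accept_proportions_by_condition(recs, common, "by_agent")
        predicted = mg.predicted_proportion_table(
            small_conditions, common, mg.DbSParams(3.0, 0.05)
        )
        merged = observed.merge(predicted, on="condition")
        # 10 agents x 4 reps x |common| trials per condition: MC error ~ 0.01
        assert (merged["proportion"] - merged["mean_accept"]).abs().max() < 0.035
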