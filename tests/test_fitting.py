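"""Maximum-likelihood estimation: determinism, diagnostics, recovery."""

import numpy as np
import pytest

import mixedgambles as mg
from mixedgambles.errors import (
    InsufficientDataError,
    InsufficientVariationError,
    InvalidInputError,
)
from mixedgambles.fitting import CPTFitResults

from conftest import by_label


@pytest.fixture(scope="module")
def one_agent_records(small_conditions):
    agent = mg.CPTAgent("a1", mg.CPTParams(alpha=0.9, beta=0.9, lam=2.0, mu=1.0, bias=0.0))
    return mg.simulate_choices(agent, by_label(small_conditions, "LL"), n_reps=4, seed=3)


class TestFitMechanics:
    def test_seeded_determinism(self, one_agent_records):
        spec = mg.FitSpec(n_starts=5, seed=9)
        r1 = mg.fit_mle(one_agent_records, spec)
        r2 = mg.fit_mle(one_agent_records, spec)
        assert r1.to_dict() == r2.to_dict()

    def test_refit_from_optimum_no_improvement(self, one_agent_records):
        spec = mg.FitSpec(n_starts=5, seed=9)
        model = mg.CPTAcceptReject.from_dataframe(one_agent_records)
        res = model.fit(spec)
        p = res.params
        theta = np.array([p.alpha, np.log(p.lam), p.mu, p.bias])
        polished = model._minimize_from(theta, spec)
        assert -polished.fun <= -res.loglik + 1e-6 + 1e-9

    def test_perfect_separation_flagged_not_raised(self, small_conditions, caplog):
        agent = mg.CPTAgent("a1", mg.CPTParams(mu=0.0, bias=30.0))
        recs = mg.simulate_choices(agent, by_label(small_conditions, "LL"), seed=0)
        assert recs["accepted"].all()
        with caplog.at_level("WARNING"):
            res = mg.fit_mle(recs, mg.FitSpec(n_starts=3, seed=0))
        assert "bias" in res.at_bound
        assert "separation" in caplog.text

    def test_summary_mentions_estimates(self, one_agent_records):
        res = mg.fit_mle(one_agent_records, mg.FitSpec(n_starts=3, seed=1))
        text = res.summary()
        assert "lambda" in text and "log-likelihood" in text
        assert res.loglik <= 0
        assert res.llf == res.loglik

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            mg.CPTAcceptReject([], [], [])
        with pytest.raises(InvalidInputError):
            mg.FitSpec(n_starts=0)
        with pytest.raises(InvalidInputError):
            mg.FitSpec(bounds={"lam": (2.0, 1.0)})


class TestParameterRecovery:
    def test_known_lambda_recovered_in_median(self, standard_conditions):
        """Agents simulated at lambda=2 are refitted near lambda=2 in the median."""
        truth = mg.CPTParams(alpha=0.9, beta=0.9, lam=2.0, mu=1.0, bias=0.0)
        ll = by_label(standard_conditions, "LL")
        lams = []
        for i in range(50):
            recs = mg.simulate_choices(mg.CPTAgent(f"a{i:03d}", truth), ll, seed=1000 + i)
            res = mg.fit_mle(recs, mg.FitSpec(n_starts=5, seed=i))
            lams.append(res.params.lam)
        assert 1.7 <= np.median(lams) <= 2.3

    def test_bias_centred_when_generated_unbiased(self, standard_conditions):
        truth = mg.CPTParams(alpha=1.0, beta=1.0, lam=1.0, mu=1.0, bias=0.0)
        ll = by_label(standard_conditions, "LL")
        biases = []
        for i in range(20):
            recs = mg.simulate_choices(
                mg.CPTAgent(f"a{i:03d}", truth), ll, n_reps=2, seed=2000 + i
            )
            biases.append(mg.fit_mle(recs, mg.FitSpec(n_starts=5, seed=i)).params.bias)
        # Monte-Carlo CI of the mean bias covers 0
        se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(np.mean(biases)) < 3 * se + 0.05


class TestLambdaBiasCorrelation:
    def _fake_fit(self, lam, bias):
        params = mg.CPTParams(alpha=1.0, beta=1.0, lam=lam, mu=1.0, bias=bias)
        return CPTFitResults(
            model=None, params=params, loglik=-1.0, converged=True,
            at_bound=frozenset(), n_trials=10, spec=None,
        )

    def test_needs_three_converged_fits(self):
        with pytest.raises(InsufficientDataError):
            mg.lambda_bias_correlation([self._fake_fit(1, 0.1), self._fake_fit(2, 0.2)])

    def test_frozen_bias_raises(self):
        fits = [self._fake_fit(lam, 0.0) for lam in (1.0, 2.0, 3.0)]
        with pytest.raises(InsufficientVariationError):
            mg.lambda_bias_correlation(fits)

    def test_tied_ranks_handled(self):
        # two distinct agents each replicated 10x: heavy ties, no error
        fits = [self._fake_fit(1.0, 0.5) for _ in range(10)]
        fits += [self._fake_fit(2.0, -0.5) for _ in range(10)]
        rho = mg.lambda_bias_correlation(fits)
        assert rho == pytest.approx(-1.0)

    def test_perfect_monotone_association(self):
        fits = [self._fake_fit(lam, lam / 10) for lam in (0.5, 1.0, 2.0, 4.0)]
        assert mg.lambda_bias_correlation(fits) == pytest.approx(1.0)
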