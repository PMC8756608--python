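"""Maximum-likelihood estimation of the prospect-theory accept-reject model.

The estimation surface follows the statsmodels convention: a model object
(:class:`CPTAcceptReject`) is built from choice data, and ``fit()`` returns
a results object (:class:`CPTFitResults`) carrying the estimates, the
log-likelihood, convergence diagnostics and a ``summary()`` table.

The likelihood over mixed gambles has a well-known ridge along the
λ-``bias`` trade-off: raising λ (rejecting because losses loom large) and
lowering ``bias`` (rejecting everything a little more) move fitted
probabilities in nearly the same direction.  Estimation therefore uses
multi-start L-BFGS-B with an analytic gradient, box constraints, and λ
optimized on the log scale (positivity, symmetric multiplicative error).
Single starts are unreliable on this surface; results are deterministic
given the data and the :class:`FitSpec` seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import spearmanr

from . import cpt
from .cpt import CPTParams, Records
from .errors import (
    InsufficientDataError,
    InsufficientVariationError,
    InvalidInputError,
)

_log = logging.getLogger(__name__)

#: Default box constraints on the natural parameter scale.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.2, 2.0),
    "beta": (0.2, 2.0),
    "lam": (0.05, 20.0),
    "mu": (0.0, 50.0),
    "bias": (-10.0, 10.0),
}

#: Absolute tolerance (scaled by max(1, |bound|)) for flagging an estimate
#: as sitting on a box constraint.
_BOUND_TOL = 1e-6


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one maximum-likelihood fit.

    bounds : box constraints per parameter (natural scale).
    alpha_equals_beta : fit a single curvature exponent (default True; λ and
        unequal curvatures trade off severely on mixed gambles).
    n_starts : number of local optimizations; the first start is a neutral
        centre (alpha=1, lam=1, mu=1, bias=0 projected into bounds), the
        rest are drawn uniformly within bounds from ``seed``.
    seed : RNG seed for the start draws.
    """

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    alpha_equals_beta: bool = True
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise InvalidInputError("n_starts must be >= 1")
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        for name, (lo, hi) in merged.items():
            if not lo < hi:
                raise InvalidInputError(f"bound for {name} must have lower < upper")
        object.__setattr__(self, "bounds", merged)

    @property
    def param_names(self) -> list[str]:
        if self.alpha_equals_beta:
            return ["alpha", "lam", "mu", "bias"]
        return ["alpha", "beta", "lam", "mu", "bias"]


class CPTAcceptReject:
    """Prospect-theory accept-reject model bound to a set of choices.

    Parameters
    ----------
    accepted : array-like of bool/0-1, one entry per trial.
    gains, losses : positive amounts per trial (losses as magnitudes).
    """

    def __init__(self, accepted, gains, losses):
        self.accepted = np.asarray(accepted).astype(bool)
        self.gains = np.asarray(gains, dtype=float)
        self.losses = np.asarray(losses, dtype=float)
        if not (self.accepted.shape == self.gains.shape == self.losses.shape):
            raise InvalidInputError("accepted, gains, losses must have equal length")
        if self.nobs == 0:
            raise InvalidInputError("model needs at least one trial")
        if np.any(self.gains <= 0) or np.any(self.losses <= 0):
            raise InvalidInputError("gains and loss magnitudes must be > 0")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "CPTAcceptReject":
        """Build from a choice table with columns gain, loss, accepted."""
        return cls(frame["accepted"].to_numpy(), frame["gain"].to_numpy(),
                   frame["loss"].to_numpy())

    @classmethod
    def from_records(cls, records: Records) -> "CPTAcceptReject":
        gains, losses, accepted = cpt.choice_arrays(records)
        return cls(accepted, gains, losses)

    @property
    def nobs(self) -> int:
        return int(self.gains.size)

    def loglike(self, params: CPTParams) -> float:
        """Clamped Bernoulli log-likelihood at ``params``."""
        frame = pd.DataFrame(
            {"gain": self.gains, "loss": self.losses, "accepted": self.accepted}
        )
        return cpt.log_likelihood(frame, params)

    # -- internal parameterization: λ on the log scale ----------------------

    def _nll_and_grad(self, theta: np.ndarray, eq: bool):
        if eq:
            a, loglam, mu, bias = theta
            b = a
        else:
            a, b, loglam, mu, bias = theta
        lam = math.exp(loglam)
        vg = self.gains**a
        vl = self.losses**b
        u = 0.5 * (vg - lam * vl)
        eta = mu * u + bias
        y = self.accepted
        # -loglik = sum log(1 + e^eta) - y*eta  (numerically exact form)
        nll = float(np.sum(np.logaddexp(0.0, eta) - np.where(y, eta, 0.0)))
        r = expit(eta) - y  # d nll / d eta
        d_bias = float(np.sum(r))
        d_mu = float(r @ u)
        d_loglam = float(-0.5 * mu * lam * (r @ vl))
        lg = np.log(self.gains)
        ll = np.log(self.losses)
        if eq:
            d_a = float(0.5 * mu * (r @ (vg * lg - lam * vl * ll)))
            grad = np.array([d_a, d_loglam, d_mu, d_bias])
        else:
            d_a = float(0.5 * mu * (r @ (vg * lg)))
            d_b = float(-0.5 * mu * lam * (r @ (vl * ll)))
            grad = np.array([d_a, d_b, d_loglam, d_mu, d_bias])
        return nll, grad

    def _internal_bounds(self, spec: FitSpec) -> list[tuple[float, float]]:
        b = spec.bounds
        lam_lo, lam_hi = b["lam"]
        core = [(math.log(lam_lo), math.log(lam_hi)), b["mu"], b["bias"]]
        if spec.alpha_equals_beta:
            return [b["alpha"]] + core
        return [b["alpha"], b["beta"]] + core

    def _minimize_from(self, theta0: np.ndarray, spec: FitSpec):
        return minimize(
            self._nll_and_grad,
            theta0,
            args=(spec.alpha_equals_beta,),
            jac=True,
            method="L-BFGS-B",
            bounds=self._internal_bounds(spec),
        )

    def _starts(self, spec: FitSpec) -> np.ndarray:
        bounds = np.array(self._internal_bounds(spec), dtype=float)
        lo, hi = bounds[:, 0], bounds[:, 1]
        if spec.alpha_equals_beta:
            centre = np.array([1.0, 0.0, 1.0, 0.0])
        else:
            centre = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        centre = np.clip(centre, lo, hi)
        rng = np.random.default_rng(spec.seed)
        random = lo + (hi - lo) * rng.random((max(spec.n_starts - 1, 0), lo.size))
        return np.vstack([centre[None, :], random])

    def fit(self, spec: FitSpec | None = None) -> "CPTFitResults":
        """Multi-start maximum-likelihood fit.

        Deterministic given the data and ``spec``.  All-accept or all-reject
        data (perfect separation) is flagged via ``at_bound`` containing
        ``"bias"`` and a logged warning, not an exception.
        """
        spec = spec or FitSpec()
        eq = spec.alpha_equals_beta
        best = None
        for theta0 in self._starts(spec):
            res = self._minimize_from(theta0, spec)
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        if eq:
            a, loglam, mu, bias = theta
            b = a
        else:
            a, b, loglam, mu, bias = theta
        params = CPTParams(alpha=a, beta=b, lam=math.exp(loglam), mu=mu, bias=bias)

        at_bound = set()
        estimates = {"alpha": a, "lam": params.lam, "mu": mu, "bias": bias}
        if not eq:
            estimates["beta"] = b
        for name, est in estimates.items():
            lo, hi = spec.bounds[name]
            tol_lo = _BOUND_TOL * max(1.0, abs(lo))
            tol_hi = _BOUND_TOL * max(1.0, abs(hi))
            if abs(est - lo) <= tol_lo or abs(est - hi) <= tol_hi:
                at_bound.add(name)
        if self.accepted.all() or (~self.accepted).all():
            at_bound.add("bias")
            _log.warning(
                "perfect separation: all %d responses are %s; bias estimate "
                "is not identified",
                self.nobs,
                "accepts" if self.accepted.all() else "rejects",
            )

        return CPTFitResults(
            model=self,
            params=params,
            loglik=self.loglike(params),
            converged=bool(best.success),
            at_bound=frozenset(at_bound),
            n_trials=self.nobs,
            spec=spec,
        )


class CPTFitResults:
    """Outcome of a maximum-likelihood fit of :class:`CPTAcceptReject`."""

    def __init__(self, model, params, loglik, converged, at_bound, n_trials, spec):
        self.model = model
        self.params: CPTParams = params
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.at_bound: frozenset[str] = frozenset(at_bound)
        self.n_trials = int(n_trials)
        self.spec = spec

    @property
    def llf(self) -> float:
        """Alias for the log-likelihood (statsmodels convention)."""
        return self.loglik

    def to_dict(self) -> dict:
        p = self.params
        return {
            "alpha": p.alpha,
            "beta": p.beta,
            "lam": p.lam,
            "mu": p.mu,
            "bias": p.bias,
            "loglik": self.loglik,
            "converged": self.converged,
            "at_bound": sorted(self.at_bound),
            "n_trials": self.n_trials,
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "CPT accept-reject maximum-likelihood fit",
            "========================================",
            f"n trials        {self.n_trials:>10d}",
            f"log-likelihood  {self.loglik:>10.3f}",
            f"converged       {str(self.converged):>10s}",
            "----------------------------------------",
            f"alpha  {p.alpha:>10.4f}",
            f"beta   {p.beta:>10.4f}",
            f"lambda {p.lam:>10.4f}",
            f"mu     {p.mu:>10.4f}",
            f"bias   {p.bias:>10.4f}",
        ]
        if self.at_bound:
            lines.append(f"at bound: {', '.join(sorted(self.at_bound))}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.params
        return (
            f"<CPTFitResults lam={p.lam:.3f} bias={p.bias:.3f} mu={p.mu:.3f} "
            f"alpha={p.alpha:.3f} loglik={self.loglik:.2f} "
            f"converged={self.converged}>"
        )


def fit_mle(records: Records, spec: FitSpec | None = None) -> CPTFitResults:
    """Fit the accept-reject model to one agent's choice records."""
    return CPTAcceptReject.from_records(records).fit(spec)


def fit_population(
    records: pd.DataFrame, spec: FitSpec | None = None
) -> dict[str, CPTFitResults]:
    """Fit each agent in a choice table independently.

    Agents are processed in sorted id order with per-agent seeds streamed
    from ``spec.seed``, so the result is deterministic and independent of
    row order.
    """
    spec = spec or FitSpec()
    fits: dict[str, CPTFitResults] = {}
    for i, (agent_id, group) in enumerate(
        sorted(records.groupby("agent_id"), key=lambda kv: str(kv[0]))
    ):
        sub_seed = int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0] & 0x7FFFFFFF)
        agent_spec = FitSpec(
            bounds=spec.bounds,
            alpha_equals_beta=spec.alpha_equals_beta,
            n_starts=spec.n_starts,
            seed=sub_seed,
        )
        fits[str(agent_id)] = CPTAcceptReject.from_dataframe(group).fit(agent_spec)
    return fits


def lambda_bias_correlation(fits: Iterable[CPTFitResults]) -> float:
    """Spearman rank correlation between λ̂ and the bias estimate across agents.

    Only converged fits are used; ties are handled by mid-ranks.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 converged fits.
    InsufficientVariationError
        λ̂ or bias is constant across fits (e.g. a frozen parameter).
    """
    usable = [f for f in fits if f.converged]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 converged fits, got {len(usable)}"
        )
    lams = np.array([f.params.lam for f in usable])
    biases = np.array([f.params.bias for f in usable])
    if np.ptp(lams) == 0 or np.ptp(biases) == 0:
        raise InsufficientVariationError(
            "lambda or bias estimates are constant across fits"
        )
    rho = spearmanr(lams, biases).statistic
    return float(rho)
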