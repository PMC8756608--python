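# Methods

## The problem

In the accept–reject task a participant sees a 50–50 mixed gamble — win a
gain *G* or lose a loss *L*, each with probability ½ — and chooses to play
or decline.  Rejection of favourable gambles is conventionally read as
*loss aversion* and quantified by prospect theory's λ.  This package
implements, as simulation and estimation machinery, two claims about that
paradigm: (1) the range of gains and losses experienced in a session
shifts acceptance of identical gambles, in the direction predicted by
rank-based (decision-by-sampling) valuation; and (2) λ estimated from
accept–reject choices is so entangled with a response bias, and so
sensitive to the composition of the choice set, that it fails to
generalize even across random halves of one balanced choice set.

## Choice-set design

A condition is the full factorial of `n_levels` equally spaced gain levels
(`max_gain·k/n_levels`, k = 1..n) and loss levels (likewise).  The 2×2
design crosses maximum gain ∈ {low, high} with maximum loss ∈ {low, high};
defaults are low = 20, high = 40 currency units with 20 levels.  These
maxima follow the published range manipulation (£0–£20 vs £0–£40); the
exact level grids of the original experiments are not printed anywhere, so
the 20-level default is this package's own choice, made so that the low
and high grids share every second level and the *common gambles* (pairs
present in all four conditions) form a non-trivial 10×10 sub-grid.
Losses are stored as positive magnitudes everywhere; sign enters only in
value functions.  Currency is abstract — no locale handling.

## Decision by sampling

The subjective magnitude of an amount is its relative rank in a comparison
pool: mid-rank under ties, with the target itself excluded from its own
pool.  This convention makes the median of a symmetric grid rank exactly
0.5 (a £10 gain "is larger than half of the gains" in a 0–20 context) and
the pool maximum rank 1.  Pools may contain 0 (an experienced zero
outcome), which is what makes the dense-grid arithmetic exact; condition
levels themselves are strictly positive.

The default comparison context is *task-endogenous*: a condition's own
attribute levels.  `uniform_pool(max, n)` provides the dense-grid
alternative over [0, max].  The theory predicts directions only, so
choices are closed with a logistic rule on the rank difference,

    P(accept) = (1 − 2·tremble) · logistic(s · (rank(G) − rank(L))) + tremble,

with sensitivity `s` (default 3) and tremble (lapse) probability 0.05.
The sensitivity default puts the most extreme common gambles around
P ≈ 0.8/0.2 — strong but noisy context effects, comparable to published
acceptance-proportion spreads; tremble 0.05 is a conventional lapse rate.
Because the rule is antisymmetric in the rank difference, symmetric
conditions (equal gain and loss grids) average to exactly 0.5 on any
common set closed under swapping gain with loss, while the asymmetric
conditions move acceptance below 0.5 (high max gain, low max loss) or
above it (low max gain, high max loss).

## Prospect-theory accept–reject model

Value function v(x) = x^α for gains, −λ·(−x)^β for losses; subjective
value U = ½v(G) + ½v(−L); choice rule P(accept) = logistic(μU + bias).
No probability weighting: both outcomes sit at ½, and any weight w(½) is
absorbed into μ.  The default fitted configuration constrains α = β,
because λ and unequal curvatures trade off severely on mixed gambles
(`alpha_equals_beta=False` frees them).  The log-likelihood clamps
probabilities to [1e−9, 1 − 1e−9] so boundary parameters stay finite.

Estimation is multi-start L-BFGS-B with an analytic gradient.  λ is
optimized on the log scale; box bounds are λ ∈ [0.05, 20], μ ∈ [0, 50],
bias ∈ [−10, 10], α ∈ [0.2, 2].  The first start is a neutral centre
(α = 1, λ = 1, μ = 1, bias = 0); the remaining `n_starts − 1` (default 10
total) are uniform in the bounds from the fit seed.  Estimates within
1e−6 (scaled) of a bound are flagged in `at_bound`; all-accept or
all-reject data additionally flags `bias` (perfect separation) with a
warning rather than an exception, because split-half experiments
routinely produce degenerate halves.  Fits are deterministic given data
and `FitSpec`.

## Synthetic populations

The generator defaults define the study conditions:

| generator | heterogeneous | fixed |
|---|---|---|
| `cpt` (well-specified) | λ ~ log-normal, median 2, log-sd 0.3; bias ~ N(0, 0.5) | μ = 1, α = β = 0.9 |
| `dbs` (misspecified)   | sensitivity ~ N(3, 0.5), truncated at 0 | tremble = 0.05 |

Median λ = 2 and α ≈ 0.9 are the canonical accept–reject population
values; the log-sd 0.3 gives a realistic inter-individual spread
(λ roughly 1.1–3.6 for 95% of agents).  Latent accept probabilities are
resolved into Bernoulli decisions.  Each agent sees a condition's full
factorial `n_reps` times; the default picks `n_reps` so every agent has at
least 256 trials (one repetition of a 20-level grid gives 400), enough
that random halves remain fittable and the split-half phenomenon cannot
be blamed on tiny samples.  A master seed streams per-agent sub-seeds via
`SeedSequence([master, agent_index, condition_index])`, so any slice of a
population reproduces independently.

What the generator does *not* emulate: sequential context (recency,
cumulative exposure across trials), response times, learning or order
effects, and real participants' departures from both model families.
Passing tests therefore show that the estimation pipeline behaves as
claimed *under these generators* — they demonstrate properties of the
method, not new facts about human choosers.

## Split-half rank generalization

Per replicate: each agent's records are split randomly in half (sizes
differ by ≤ 1); λ is fitted on half A; agents are ranked by λ̂ (ascending,
ties broken by agent id); the agents at the 5th/25th/50th/75th/95th
percentiles are located by nearest rank (⌈p·n/100⌉); λ is refitted on
half B and the target agents' new ranks recorded.  Aggregation over
replicates (default 50; the experiment's tests use 20) yields the rank
distributions, alongside the Spearman correlation of λ̂ between halves.

The *stochasticity-only null* regenerates half-B choices from each
agent's own half-A fitted probabilities (the generator *is* the fitted
model), refits and re-ranks: the rank dispersion expected purely from
Bernoulli resolution of latent probabilities.  Spread beyond the null is
attributable to the interaction of model misspecification with the
choice-set change.

Agents whose fit on either half failed to converge, pinned λ at a box
bound, or showed perfect separation are excluded from that replicate's
ranking (with a warning past 20% drops; an error below 10 usable agents).
α or μ sitting on a bound does not exclude an agent: a pinned curvature
still yields a usable λ rank, and excluding on it would routinely
decimate misspecified fits.

## Numerical and design choices

- Level grids are rounded to 12 decimals at construction so that levels
  shared between conditions compare exactly equal across float paths.
- The fitting objective uses the exact `log(1+e^η)` form internally
  (no clamping needed); the reported log-likelihood uses the public
  clamped definition.  The two differ only at absurd parameter values.
- A rank against an empty comparison set (a pool containing only the
  target itself) returns 0.5 — indifference — rather than raising.
- Whether the original split-half analysis ranked within one replicate or
  averaged many is not something this package can settle; it aggregates
  over replicates by default and supports `n_replicates=1`.
- The experiment-scale tests use 50 agents, 400 trials per agent and 20
  split replicates with 5 optimizer starts per fit — sizes at which the
  rank-generalization contrast is stable while a full run of the suite
  stays at desk scale.

## Pipeline configuration (YAML)

`mixedgambles run config.yaml` accepts:

```yaml
seed: 3              # master seed for population, choices, fits
outdir: pipeline_out
design:    {low: 20, high: 40, levels: 20}
population: {n_agents: 50, generator: dbs, hyperparams: {}}
simulate:  {reps: null, assignment: between}   # reps null => >= 256 trials
recover:   {replicates: 50, n_starts: 10, null: true}   # omit to skip
```

Artifacts (conditions, choices, predicted/observed proportions, fits,
recovery report) are CSV/JSON with a manifest recording the config hash,
seeds and package versions.

## Known limitations

- The DbS choice rule (logistic + tremble) is one closure among several;
  directional predictions do not depend on it but exact proportions do.
- No hierarchical estimation or standard errors: ranks and medians, not
  confidence intervals, are the objects of interest here.
- Comparison pools are static within a condition; trial-by-trial memory
  sampling dynamics are out of scope.
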