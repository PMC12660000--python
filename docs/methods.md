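# Methods

`actionmsm` models timestamped action-sequence logs from computer-based
problem-solving assessments as a multi-state survival process: every logged
action is a state, and the time between consecutive actions is a sojourn
whose hazard of ending in a particular next action carries the science.

## Model

For respondent $i$ (correctness group $g_i \in \{0,1\}$, covariates
$x_i \in \mathbb{R}^p$) the hazard of a transition from action $m$ to action
$l$ is

$$
h_i^{ml} \;=\; \lambda_{ml g_i}\,\theta_i\,
\exp\!\big(x_i^\top\beta + \gamma_{1 g_i}\,\mathbb{1}[m \in K]
          + \gamma_{2 g_i}\,\mathbb{1}[l \in K]\big),
$$

with group-specific baseline rates $\lambda$ (per minute), a person speed
factor $\theta_i > 0$, covariate effects $\beta$ shared across groups and
transitions, and start/end key-action effects $\gamma_1, \gamma_2$ for the
key set $K$. Rates are constant in time (time-homogeneous Markov
assumption), so

* sojourns in state $m$ are exponential with rate $\sum_l h_i^{ml}$;
* the log-likelihood reduces to transition counts $d_{iml}$ and state
  exposure times $e_{im}$:
  $\ell = \sum_i \big[\sum_{(m,l)} d_{iml}\ln h_i^{ml}
   - \sum_m e_{im} \sum_l h_i^{ml}\big]$, with the final sojourn
  right-censored at the total solution time $T_i$;
* the embedded-chain next-action probability is
  $P_i^{ml} = h_i^{ml} / \sum_{l'} h_i^{ml'}$, in which $\theta_i$,
  $\exp(x_i^\top\beta)$ and the $\gamma_1$ source term cancel row-wise —
  group comparisons of $P$ depend only on the $\lambda$'s and $\gamma_2$.

The time before the first logged action is not modelled (a respondent
enters the state of their first action at that action's timestamp), and
repeated identical consecutive events are kept as observable
self-transitions by default; `collapse_repeats` provides the classical
continuous-time-Markov alternative in which self-loops are merged away.

**Support.** With dozens of actions, most of the $E \times E \times 2$
baseline-rate grid carries no data. The default `observed` policy restricts
each group's rate parameters to the ordered pairs actually seen in that
group (structural zeros elsewhere), which keeps the model identified and
the sampler fast; the `full` policy opens all pairs and is what the
simulator generates under.

## Key-action extraction

The text-mining analogy treats sequences as documents and actions as terms.
Inverse sequence frequency $\mathrm{ISF}_i = \ln(N/n_i)$ uses the number of
sequences containing action $i$ (document-frequency reading; a
total-occurrence variant is switchable), with the natural logarithm. Weights
$w_{ij} = \mathrm{TF}_{ij}\,\mathrm{ISF}_i$ are summed per group into a 2x2
table per action (weighted occurrences vs. the group's remaining weighted
mass), scored by the Pearson chi-square statistic without continuity
correction. Non-integer "counts" are used as-is — the scores only rank
actions, no p-values are attached. An action is a key-action candidate when
its weighted share in the correct group exceeds its share in the incorrect
group. The default cut-off is the elbow of the descending score curve (the
point furthest from the chord joining the first and last points, in rank /
score coordinates); selection keeps candidates whose score is *strictly*
greater than the elbow action's score, so the elbow itself is excluded.
Ties in ranking break alphabetically, making the output deterministic.

## Estimation

Fully Bayesian, by Metropolis-within-Gibbs with one block per scalar
parameter. $\lambda$ and $\theta$ blocks use Gaussian random walks on the
log scale (Jacobian included in the acceptance ratio); $\beta$ and $\gamma$
use plain Gaussian random walks. Because the likelihood factorizes over the
sufficient statistics, every block's acceptance ratio is evaluated from
cached aggregates: all $\lambda$ blocks (conditionally independent given the
rest) and all $\theta$ blocks update as single vectorized sweeps, and each
$\beta$/$\gamma$ update is one O(N) reduction.

Priors: $\beta_k, \gamma \sim \mathcal{N}(0, \sigma^2)$ with
$\sigma_\beta = \sigma_\gamma = 2$ by default — posterior inference is
stable for $\sigma \ge 2$, which the `sensitivity_sweep` operation can
verify on any dataset; $\lambda, \theta \sim \mathrm{Gamma}(1, 1)$
(shape, scale; prior mean 1). The likelihood is invariant under
$\lambda \mapsto c\lambda$, $\theta \mapsto \theta/c$; the
$\mathrm{Gamma}(1,1)$ prior on the $N$ person speeds pins that common scale
softly. For reporting, `mean_parameter_set(renormalize=True)` rescales each
draw so the geometric mean of the speeds is exactly 1.

**Adaptation.** During burn-in only, every `adapt_interval` (default 100)
iterations each block's proposal sd is multiplied by 1.5 if its windowed
acceptance rate exceeds 0.5 and by 0.67 if below 0.2; proposals are frozen
after burn-in, so the post-burn-in kernel is a valid time-homogeneous
Metropolis chain targeting the exact posterior. Initial values: $\lambda$
at empirical rates $d_{+ml,g}/e_{+m,g}$ floored at $10^{-3}$, $\theta = 1$,
$\beta = \gamma = 0$.

Defaults are desk-scale (20,000 iterations, 5,000 burn-in, thin 5, 5
chains); `MCMCConfig.large_scale()` gives the large preset
(300,000/100,000/thin 10/5 chains) appropriate for full-size assessments.
Chains are seeded `seed + chain_index`; identical configs reproduce draws
bit-for-bit.

**Inference rules.** Convergence is the classic (non-split) Gelman–Rubin
$\hat{R} = \sqrt{((n-1)/n\,W + B/n)/W}$ per scalar, with the conventional
1.1 threshold. Interval estimates are highest-posterior-density intervals
(shortest window over the sorted draws containing $\lceil 0.95 n\rceil$
draws); an effect is "significant" when its 95% HPD excludes zero. Group
differences in transition probabilities are computed per draw and summarized
the same way; pairs supported in only one group are excluded rather than
imputed (imputing would compare data to prior). No multiplicity correction
is applied across pairs.

## Synthetic-data generator

`generate` draws, per individual: group $\sim$ Bernoulli(0.5); covariates
i.i.d. $\mathcal{N}(0, 4)$; speed $\theta_i \sim \mathrm{Gamma}(1,1)$;
sequence length $J_i \sim \mathrm{NegBin}(r{=}5, p{=}0.15)$ (mean ~28,
over-dispersed like real per-item action counts), truncated at $\ge 2$;
initial state uniform. It then walks the continuous-time mechanism over the
full $E \times E$ support and draws one extra sojourn after the last action
to set $T_i$, so the final exposure is right-censored exactly as in real
logs. True baseline rates are log-uniform on $[0.5, 2]$ per pair, drawn
from a dedicated `lam_seed` so the truth is fixed while data seeds vary.

Scenario presets: **S1** no group differences, no key effects,
$\beta = (\pm 0.1, \dots)$; **S2** shared key effects
$\gamma_1 = \gamma_2 = 0.3$; **S3** the correct group's rate doubled on a
fixed random 20% of pairs; **S4** that heterogeneity plus group-specific
$\gamma = (-0.3, +0.3)$. The preset magnitudes are this package's choices;
they produce detectable but not overwhelming structure at a few hundred
respondents.

What the generator does *not* emulate: interface constraints (in real
assessment items many transitions are impossible; here all are open),
semantically meaningful action labels, non-exponential within-state dwell
times, and respondent disengagement. Passing recovery tests therefore shows
the estimator inverts its own generative model at realistic sizes — not
that real logs satisfy the time-homogeneity or proportional-hazards
assumptions.

**Recovery metric.** Per individual, the mean of squared element-wise
differences between estimated (posterior-mean plug-in) and true
transition-probability matrices over all $E^2$ entries, then averaged over
individuals; `run_replications` repeats generate→fit→score with
incremented seeds.

## Numerical choices and edge cases

* Degenerate 2x2 margins (an expected cell of 0) score chi-square 0; the
  elbow is undefined for fewer than two actions or an all-equal score curve
  (explicit error directing to `top_k`/`min_score`).
* Tied timestamps keep file order (stable sort); the log format is CSV with
  times in decimal minutes, read with round-trip float parsing so
  write→read is byte-exact.
* A respondent with a single event contributes exposure but no transitions;
  a transition observed on a pair with hazard 0 yields $-\infty$
  log-likelihood (support violation, surfaced rather than clipped).
* Transition-matrix rows whose source has no supported destination are NaN
  (flagged), not renormalized; for MSE evaluation they count as zeros on the
  full grid.
* HPD intervals require $\ge 20$ draws; Gelman–Rubin $\ge 2$ chains and
  $\ge 10$ draws.

## Problem sizes used in the shipped studies

The validation suite and the reproduction script use a reduced study: 100
individuals, 10 actions (2 key), 2 covariates, 5 chains x 5,000 iterations
(2,000 burn-in, thin 5) for convergence/tuning checks, and 8–20
replications at N ∈ {25, 50, 100} with single 1,500-iteration chains for
recovery. These sizes give Monte-Carlo error well below the decision
thresholds they are checked against while keeping each study in seconds.

## Known limitations

* Time-homogeneity: hazards are constant within and across sojourns;
  semi-Markov or time-varying extensions are out of scope.
* The $\lambda\theta$ scale is only softly identified; reported $\lambda$
  magnitudes depend on the $\theta$ prior centering (the embedded-chain
  probabilities do not).
* Group comparison requires both groups to have observed a pair; rarely
  visited transitions are silently absent from the comparison table (listed
  under `excluded`).
* The sampler is single-threaded; large-scale runs (hundreds of thousands
  of iterations, 100+ states) take hours, not seconds.
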