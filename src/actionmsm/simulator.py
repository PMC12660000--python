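"""Synthetic log-data generation from the transition model.

The generator draws, per individual: a correctness group, i.i.d. Normal
covariates, a Gamma person speed, a negative-binomial sequence length
(truncated at 2), and then walks the continuous-time mechanism — from state m
the sojourn is Exponential with rate equal to the total outgoing hazard and
the next state is chosen with probability proportional to the per-destination
hazards.  One extra sojourn after the last action sets the total solution
time, so the final state's exposure is right-censored exactly as in real
logs.  All E x E transitions (including self-transitions) are possible.

Four scenario presets span increasing structure:

  S1  no group differences, no key-action effects, nonzero covariate effects;
  S2  key-action effects shared by both groups;
  S3  group-heterogeneous baseline rates, no key-action effects;
  S4  group-heterogeneous baseline rates and group-specific key-action effects.

``run_replications`` wires generate -> fit -> plug-in transition matrices ->
mean squared error, the parameter-recovery loop used to validate estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .log_io import ActionEvent, LogDataset, RespondentRecord
from .msm_core import ParameterSet, transition_matrix
from . import bayes_fit

__all__ = [
    "ScenarioSpec",
    "make_scenario",
    "generate",
    "evaluate_mse",
    "run_replications",
    "transition_matrices_by_respondent",
]

_SCENARIOS = ("S1", "S2", "S3", "S4")


def _default_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"a{j:0{width}d}" for j in range(1, n + 1)]


@dataclass
class ScenarioSpec:
    """Generative configuration for one simulation scenario.

    Defaults mirror the reference study conditions: 400 individuals, 50
    actions of which the first 10 are key actions, five Normal(0, 4)
    covariates, over-dispersed negative-binomial sequence lengths (r=5,
    p=0.15, mean ~28), equal group split.  True baseline rates are drawn
    log-uniformly on [0.5, 2] per action pair from ``lam_seed`` (kept apart
    from ``seed`` so the truth is reproducible across replications).
    """

    scenario_id: str = "S1"
    n_individuals: int = 400
    n_actions: int = 50
    n_key_actions: int = 10
    n_covariates: int = 5
    covariate_sd: float = 2.0
    seqlen_r: float = 5.0
    seqlen_p: float = 0.15
    group_prob: float = 0.5
    beta: np.ndarray | None = None
    gamma1: tuple[float, float] = (0.0, 0.0)
    gamma2: tuple[float, float] = (0.0, 0.0)
    theta_shape: float = 1.0
    theta_scale: float = 1.0
    lam_low: float = 0.5
    lam_high: float = 2.0
    hetero_frac: float = 0.0
    hetero_factor: float = 2.0
    seed: int = 0
    lam_seed: int = 1234
    action_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_actions < 2:
            raise ValueError("need at least 2 actions")
        if not 0 < self.group_prob < 1:
            raise ValueError("group_prob must be in (0, 1)")
        if not 0 < self.seqlen_p < 1:
            raise ValueError("seqlen_p must be in (0, 1)")
        if not self.action_labels:
            self.action_labels = _default_labels(self.n_actions)
        if len(self.action_labels) != self.n_actions:
            raise ValueError("action_labels length must equal n_actions")
        # the default key count caps at the action count for small vocabularies
        self.n_key_actions = min(self.n_key_actions, self.n_actions)
        if self.beta is None:
            signs = np.array([1.0 if k % 2 == 0 else -1.0
                              for k in range(self.n_covariates)])
            self.beta = 0.1 * signs
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != self.n_covariates:
            raise ValueError("beta length must equal n_covariates")

    @property
    def key_set(self) -> list[str]:
        return self.action_labels[: self.n_key_actions]


def make_scenario(scenario_id: str, **overrides) -> ScenarioSpec:
    """Build one of the four scenario presets, with field overrides.

    S2 uses shared key-action effects gamma1 = gamma2 = 0.3 in both groups;
    S3 multiplies the correct group's baseline rate by 2 on a fixed random
    20% of action pairs; S4 combines that heterogeneity with group-specific
    effects gamma1 = (-0.3, 0.3), gamma2 = (-0.3, 0.3).
    """
    sid = scenario_id.upper()
    if sid not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of "
                         f"{_SCENARIOS}")
    presets: dict[str, dict] = {
        "S1": {},
        "S2": {"gamma1": (0.3, 0.3), "gamma2": (0.3, 0.3)},
        "S3": {"hetero_frac": 0.2},
        "S4": {"hetero_frac": 0.2, "gamma1": (-0.3, 0.3),
               "gamma2": (-0.3, 0.3)},
    }
    kwargs = {"scenario_id": sid, **presets[sid]}
    kwargs.update(overrides)
    return ScenarioSpec(**kwargs)


def true_parameter_lambdas(spec: ScenarioSpec) -> dict[int, np.ndarray]:
    """True baseline-rate matrices per group (E x E, full support)."""
    rng = np.random.default_rng(spec.lam_seed)
    e = spec.n_actions
    base = np.exp(rng.uniform(np.log(spec.lam_low), np.log(spec.lam_high),
                              size=(e, e)))
    lam = {0: base, 1: base.copy()}
    if spec.hetero_frac > 0.0:
        n_cells = e * e
        n_het = int(round(spec.hetero_frac * n_cells))
        cells = rng.choice(n_cells, size=n_het, replace=False)
        flat = lam[1].ravel()
        flat[cells] *= spec.hetero_factor
        lam[1] = flat.reshape(e, e)
    return lam


def generate(spec: ScenarioSpec) -> tuple[LogDataset, ParameterSet]:
    """Generate a dataset and the true parameters that produced it."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.action_labels
    e = spec.n_actions
    lam_mats = true_parameter_lambdas(spec)
    kvec = np.array([a in set(spec.key_set) for a in labels])

    records: list[RespondentRecord] = []
    theta_true: dict[str, float] = {}
    width = len(str(spec.n_individuals))
    for i in range(spec.n_individuals):
        rid = f"r{i + 1:0{width}d}"
        g = int(rng.random() < spec.group_prob)
        x = rng.normal(0.0, spec.covariate_sd, size=spec.n_covariates)
        theta = float(rng.gamma(spec.theta_shape, spec.theta_scale))
        j_i = 0
        while j_i < 2:
            j_i = int(rng.negative_binomial(spec.seqlen_r, spec.seqlen_p))
        person = theta * float(np.exp(x @ spec.beta))
        g1, g2 = spec.gamma1[g], spec.gamma2[g]
        dest_fac = np.exp(g2 * kvec)  # per-destination key boost

        state = int(rng.integers(e))
        t = 0.0
        events = [ActionEvent(labels[state], 0.0)]
        for _ in range(j_i - 1):
            rates = lam_mats[g][state] * dest_fac * person
            if kvec[state]:
                rates = rates * np.exp(g1)
            total = rates.sum()
            if not np.isfinite(total) or total <= 0.0:
                raise ValueError(f"degenerate hazards out of state "
                                 f"{labels[state]!r}")
            t += rng.exponential(1.0 / total)
            state = int(rng.choice(e, p=rates / total))
            events.append(ActionEvent(labels[state], t))
        # right-censored final sojourn sets the total time
        rates = lam_mats[g][state] * dest_fac * person
        if kvec[state]:
            rates = rates * np.exp(g1)
        total_time = t + rng.exponential(1.0 / rates.sum())
        records.append(RespondentRecord(
            id=rid, events=events, total_time=float(total_time), group=g,
            covariates=x))
        theta_true[rid] = theta

    cov_names = [f"x{k + 1}" for k in range(spec.n_covariates)]
    dataset = LogDataset(records=records, vocabulary=list(labels),
                         covariate_names=cov_names)
    full = frozenset((m, l) for m in labels for l in labels)
    lam = {}
    for g in (0, 1):
        for a, m in enumerate(labels):
            for b, l in enumerate(labels):
                lam[(m, l, g)] = float(lam_mats[g][a, b])
    truth = ParameterSet(
        support={0: full, 1: full}, lam=lam, theta=theta_true,
        beta=spec.beta.copy(),
        gamma1={0: spec.gamma1[0], 1: spec.gamma1[1]},
        gamma2={0: spec.gamma2[0], 1: spec.gamma2[1]},
        key_set=frozenset(spec.key_set), states=list(labels))
    return dataset, truth


def transition_matrices_by_respondent(params: ParameterSet,
                                      dataset: LogDataset) -> list[np.ndarray]:
    """Plug-in embedded-chain matrix per respondent (depends on group only).

    Rows whose source state has no supported destination are returned as
    zeros so matrices are comparable on the full E x E grid.
    """
    per_group: dict[int, np.ndarray] = {}
    for g in set(dataset.groups().tolist()):
        p = transition_matrix(params, g)
        per_group[g] = np.nan_to_num(p, nan=0.0)
    return [per_group[rec.group] for rec in dataset.records]


def evaluate_mse(estimated: Sequence[np.ndarray],
                 true: Sequence[np.ndarray]) -> float:
    """Mean over individuals of the per-individual mean squared entry error.

    Each individual's matrices are compared element-wise over the full
    n_actions^2 grid (unsupported cells are zeros), averaged, and the
    individual averages are then averaged.
    """
    if len(estimated) != len(true):
        raise ValueError("matrix lists differ in length")
    per_ind = []
    for est, tru in zip(estimated, true):
        est = np.asarray(est, dtype=float)
        tru = np.asarray(tru, dtype=float)
        if est.shape != tru.shape:
            raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
        per_ind.append(float(((est - tru) ** 2).mean()))
    return float(np.mean(per_ind))


def run_replications(spec: ScenarioSpec, n_reps: int,
                     fit_config: "bayes_fit.MCMCConfig",
                     priors: "bayes_fit.PriorSpec | None" = None,
                     support_policy: str = "observed") -> list[float]:
    """Generate -> fit -> evaluate recovery, repeated ``n_reps`` times.

    Replication r uses data seed ``spec.seed + r`` (the true parameters stay
    fixed via ``lam_seed``) and fit seed ``fit_config.seed + r``.  Returns
    one transition-matrix MSE per replication; the key actions are supplied
    to the fit as known.
    """
    mses = []
    for r in range(n_reps):
        rep_spec = replace(spec, seed=spec.seed + r)
        dataset, truth = generate(rep_spec)
        cfg = replace(fit_config, seed=fit_config.seed + r)
        samples = bayes_fit.fit(dataset, rep_spec.key_set, priors=priors,
                                config=cfg, support_policy=support_policy)
        est = samples.mean_parameter_set()
        est_mats = transition_matrices_by_respondent(est, dataset)
        true_mats = transition_matrices_by_respondent(truth, dataset)
        mses.append(evaluate_mse(est_mats, true_mats))
    return mses
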