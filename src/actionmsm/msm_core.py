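"""The multi-state survival model for action transitions.

Each logged action is a state of a time-homogeneous Markov multi-state model.
The hazard of respondent i moving from action m to action l is

    h_i(m -> l) = lambda[m,l,g_i] * theta_i
                  * exp( x_i . beta + gamma1[g_i] 1[m in K] + gamma2[g_i] 1[l in K] )

with group-specific baseline rates lambda (per minute), a person speed factor
theta_i, shared covariate effects beta, and key-action start/end effects
gamma1/gamma2 for the key set K.  Rates are constant over time, so sojourns
are exponential, the likelihood reduces to transition counts and state
exposure times, and the embedded-chain transition probability is

    P_i(m -> l) = h_i(m -> l) / sum_l' h_i(m -> l') ,

in which theta_i, exp(x_i . beta) and the gamma1 source term cancel row-wise:
P depends only on the group's lambdas and gamma2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .log_io import LogDataset

__all__ = [
    "SufficientStatistics",
    "ParameterSet",
    "compute_sufficient_statistics",
    "hazard_rate",
    "log_likelihood",
    "transition_matrix",
]


@dataclass
class SufficientStatistics:
    """Per-respondent transition counts and state exposure times.

    ``counts[rid][(m, l)]`` is the number of observed m -> l transitions;
    ``exposure[rid][m]`` the total time (minutes) spent occupying state m,
    including the right-censored interval from the last event to the total
    solution time.  ``group`` and ``covariates`` are carried along so the
    likelihood can be evaluated from the statistics alone.
    """

    counts: dict[str, dict[tuple[str, str], int]]
    exposure: dict[str, dict[str, float]]
    group: dict[str, int]
    covariates: dict[str, np.ndarray]
    respondent_ids: list[str] = field(default_factory=list)

    def n_transitions(self, rid: str) -> int:
        return sum(self.counts[rid].values())


@dataclass
class ParameterSet:
    """A full parameter assignment for the transition model.

    ``support[g]`` is the set of permitted ordered pairs for group g and
    ``lam`` is defined exactly on those pairs.  ``states`` fixes the state
    ordering used by :func:`transition_matrix`.
    """

    support: dict[int, frozenset[tuple[str, str]]]
    lam: dict[tuple[str, str, int], float]
    theta: dict[str, float]
    beta: np.ndarray
    gamma1: dict[int, float]
    gamma2: dict[int, float]
    key_set: frozenset[str]
    states: list[str]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.key_set = frozenset(self.key_set)
        for (m, l, g), v in self.lam.items():
            if v <= 0:
                raise ValueError(f"lambda[{m}->{l}, g={g}] must be positive")
            if (m, l) not in self.support[g]:
                raise ValueError(f"lambda defined off support: {(m, l, g)}")
        for g, pairs in self.support.items():
            for pair in pairs:
                if (*pair, g) not in self.lam:
                    raise ValueError(f"missing lambda for supported pair {pair}, g={g}")
        for rid, th in self.theta.items():
            if th <= 0:
                raise ValueError(f"theta[{rid}] must be positive")


def compute_sufficient_statistics(
    dataset: LogDataset, support_policy: str = "observed",
) -> tuple[SufficientStatistics, dict[int, frozenset[tuple[str, str]]]]:
    """Reduce a dataset to transition counts, exposures, and support sets.

    Consecutive events (s_{j-1} @ t_{j-1}, s_j @ t_j) contribute one
    s_{j-1} -> s_j count and t_j - t_{j-1} exposure in s_{j-1}; the trailing
    interval up to total_time adds censored exposure to the last state.  A
    single-event respondent contributes exposure only.

    ``support_policy``:
      * ``"observed"`` (default): per group, the pairs observed at least once
        in that group.  Keeps the parameter space identified when most of the
        E x E grid carries no data.
      * ``"full"``: all E x E ordered pairs (including self-transitions) for
        both groups, as in simulation studies where any transition may occur.
    """
    counts: dict[str, dict[tuple[str, str], int]] = {}
    exposure: dict[str, dict[str, float]] = {}
    group: dict[str, int] = {}
    covs: dict[str, np.ndarray] = {}
    observed: dict[int, set[tuple[str, str]]] = {0: set(), 1: set()}
    for rec in dataset.records:
        c: dict[tuple[str, str], int] = {}
        e: dict[str, float] = {}
        evs = rec.events
        for prev, nxt in zip(evs, evs[1:]):
            pair = (prev.action, nxt.action)
            c[pair] = c.get(pair, 0) + 1
            e[prev.action] = e.get(prev.action, 0.0) + (nxt.time - prev.time)
            observed[rec.group].add(pair)
        last = evs[-1]
        e[last.action] = e.get(last.action, 0.0) + (rec.total_time - last.time)
        counts[rec.id] = c
        exposure[rec.id] = e
        group[rec.id] = rec.group
        covs[rec.id] = rec.covariates
    if support_policy == "observed":
        support = {g: frozenset(pairs) for g, pairs in observed.items()}
    elif support_policy == "full":
        full = frozenset((m, l) for m in dataset.vocabulary
                         for l in dataset.vocabulary)
        support = {0: full, 1: full}
    else:
        raise ValueError(f"unknown support policy {support_policy!r}")
    stats = SufficientStatistics(
        counts=counts, exposure=exposure, group=group, covariates=covs,
        respondent_ids=[r.id for r in dataset.records])
    return stats, support


def hazard_rate(params: ParameterSet, group: int, theta_i: float,
                x_i: np.ndarray, m: str, l: str) -> float:
    """Transition hazard (per minute) from action m to l for one respondent.

    Pairs outside the group's support are structural zeros (rate 0).
    """
    if (m, l) not in params.support[group]:
        return 0.0
    x_i = np.asarray(x_i, dtype=float)
    lin = float(x_i @ params.beta) if x_i.size else 0.0
    if m in params.key_set:
        lin += params.gamma1[group]
    if l in params.key_set:
        lin += params.gamma2[group]
    return params.lam[(m, l, group)] * theta_i * math.exp(lin)


def log_likelihood(params: ParameterSet, stats: SufficientStatistics) -> float:
    """Log-likelihood of the transition model given sufficient statistics.

    l = sum_i [ sum_(m,l) d_iml ln h_i(m->l)  -  sum_m e_im sum_l h_i(m->l) ].

    A positive count on a pair with zero hazard (off-support) yields -inf,
    signalling a support violation.
    """
    total = 0.0
    for rid in stats.respondent_ids:
        g = stats.group[rid]
        th = params.theta[rid]
        x = stats.covariates[rid]
        for (m, l), d in stats.counts[rid].items():
            h = hazard_rate(params, g, th, x, m, l)
            if h <= 0.0:
                return -math.inf
            total += d * math.log(h)
        for m, e in stats.exposure[rid].items():
            out = 0.0
            for (mm, l) in params.support[g]:
                if mm == m:
                    out += hazard_rate(params, g, th, x, m, l)
            total -= e * out
    return total


def transition_matrix(params: ParameterSet, group: int, theta_i: float = 1.0,
                      x_i: np.ndarray | None = None) -> np.ndarray:
    """Embedded-chain transition probability matrix for one group.

    Entry (m, l) is P(next action = l | current action = m), ordered as
    ``params.states``.  Rows sum to 1 over the group's supported
    destinations.  ``theta_i`` and ``x_i`` are accepted for interface
    symmetry with the hazard but cancel within each row; rows whose source
    state has no supported destination are NaN (flagged, not silently
    renormalized).
    """
    states = params.states
    idx = {s: i for i, s in enumerate(states)}
    e = len(states)
    if x_i is None:
        x_i = np.zeros(params.beta.shape)
    h = np.zeros((e, e))
    for (m, l) in params.support[group]:
        h[idx[m], idx[l]] = hazard_rate(params, group, theta_i, x_i, m, l)
    row_sums = h.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = h / row_sums
    p[row_sums[:, 0] == 0.0] = np.nan
    return p
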