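import numpy as np
import pytest

import actionmsm as am
from actionmsm.log_io import ActionEvent, LogDataset, RespondentRecord


def make_record(rid, seq, total_time=None, group=0, covariates=()):
    """Build a RespondentRecord from [(action, time), ...]."""
    events = [ActionEvent(a, t) for a, t in seq]
    if total_time is None:
        total_time = events[-1].time
    return RespondentRecord(id=rid, events=events, total_time=total_time,
                            group=group, covariates=np.asarray(covariates, float))


def random_dataset(rng, n=6, states=("a", "b", "c"), p=1, max_len=8):
    """Small random dataset with both groups represented."""
    records = []
    for i in range(n):
        length = int(rng.integers(2, max_len + 1))
        actions = rng.choice(states, size=length)
        times = np.sort(rng.uniform(0, 5, size=length))
        rec = make_record(
            f"r{i}", list(zip(actions, times)),
            total_time=float(times[-1] + rng.uniform(0, 1)),
            group=int(i % 2), covariates=rng.normal(size=p))
        records.append(rec)
    return LogDataset(records=records, vocabulary=list(states),
                      covariate_names=[f"x{k}" for k in range(p)])


def random_parameter_set(rng, dataset, support, key_set=frozenset()):
    """Random positive parameters on a given support."""
    lam = {(m, l, g): float(rng.uniform(0.2, 3.0))
           for g, pairs in support.items() for (m, l) in pairs}
    theta = {rec.id: float(rng.uniform(0.3, 3.0)) for rec in dataset.records}
    p = dataset.n_covariates
    return am.ParameterSet(
        support=support, lam=lam, theta=theta,
        beta=rng.normal(0, 0.5, size=p),
        gamma1={0: float(rng.normal(0, 0.3)), 1: float(rng.normal(0, 0.3))},
        gamma2={0: float(rng.normal(0, 0.3)), 1: float(rng.normal(0, 0.3))},
        key_set=frozenset(key_set), states=list(dataset.vocabulary))


@pytest.fixture(scope="session")
def s1_reduced():
    """Reduced scenario-S1 study: 100 individuals, 10 actions, 2 key actions."""
    spec = am.make_scenario("S1", n_individuals=100, n_actions=10,
                            n_key_actions=2, n_covariates=2, seed=1)
    dataset, truth = am.generate(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def s1_fit(s1_reduced):
    """Five-chain fit of the reduced S1 dataset (shared across tests)."""
    spec, dataset, _ = s1_reduced
    config = am.MCMCConfig(n_iter=5000, burn_in=2000, thin=5, n_chains=5,
                           seed=7)
    return am.fit(dataset, spec.key_set, config=config)
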