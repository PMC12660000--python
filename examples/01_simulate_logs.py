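"""Generate a synthetic action log and look at its shape.

Draws a no-group-difference scenario (S1): every respondent walks a
continuous-time Markov chain over 10 actions, with exponential sojourns
whose rates depend on covariates and a personal speed factor.
"""

import numpy as np

import actionmsm as am

spec = am.make_scenario("S1", n_individuals=100, n_actions=10,
                        n_key_actions=2, n_covariates=2, seed=1)
dataset, truth = am.generate(spec)

lengths = np.array([r.n_events for r in dataset.records])
times = np.array([r.total_time for r in dataset.records])
print(f"respondents:        {dataset.n_respondents}")
print(f"action vocabulary:  {dataset.n_actions} states "
      f"({', '.join(dataset.vocabulary[:4])}, ...)")
print(f"events per person:  mean {lengths.mean():.1f}, "
      f"range {lengths.min()}-{lengths.max()}")
print(f"solution time:      mean {times.mean():.2f} min")

rec = dataset.records[0]
shown = " - ".join(f"{e.action} ({e.time:.2f})" for e in rec.events[:5])
print(f"\nfirst respondent ({rec.id}, group={rec.group}): {shown} ...")
print("(actions with the minute they occurred, as in an assessment log file)")

# sufficient statistics: the model only ever sees counts and exposures
stats, support = am.compute_sufficient_statistics(dataset)
n_pairs = {g: len(s) for g, s in support.items()}
print(f"\nobserved transition pairs per group: {n_pairs}")
print("each pair's count and each state's occupancy time are the "
      "sufficient statistics of the fit")
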