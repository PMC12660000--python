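"""Parameter-recovery study: how well does the fit recover the truth?

Repeats generate -> fit -> compare for several replications and sample
sizes, scoring each run by the mean squared difference between estimated
and true per-individual transition-probability matrices (averaged over all
matrix entries, then over individuals).
"""

import numpy as np

import actionmsm as am

config = am.MCMCConfig(n_iter=1500, burn_in=500, thin=5, n_chains=1, seed=101)

print(f"{'N':>5} {'reps':>5} {'median MSE':>12} {'max MSE':>10}")
for n, reps in [(25, 5), (50, 5), (100, 10)]:
    spec = am.make_scenario("S1", n_individuals=n, n_actions=10,
                            n_key_actions=2, n_covariates=2, seed=1)
    mses = am.run_replications(spec, reps, config)
    print(f"{n:>5} {reps:>5} {np.median(mses):>12.5f} {max(mses):>10.5f}")

print("\neach MSE averages squared errors over all 100 entries of the 10x10 "
      "transition matrix;")
print("values near zero mean the embedded-chain structure is recovered, and "
      "the error shrinks as the sample grows")
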