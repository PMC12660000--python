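"""Score actions by how strongly they separate correct from incorrect
responders, and pick the key actions.

Builds a small log where action "sort" is used mostly by the correct group
and "help" mostly by the incorrect group, then runs the TF-ISF-weighted
chi-square ranking with elbow selection.
"""

import numpy as np

import actionmsm as am
from actionmsm.log_io import ActionEvent, LogDataset, RespondentRecord

rng = np.random.default_rng(0)
records = []
for i in range(60):
    group = i % 2
    actions = ["start"]
    if group == 1:
        actions += ["sort"] * int(rng.integers(1, 4)) + ["check"]
    else:
        actions += ["help"] * int(rng.integers(1, 3))
    if rng.random() < 0.5:
        actions.append("scroll")
    actions.append("submit")
    times = np.cumsum(rng.exponential(0.3, size=len(actions)))
    events = [ActionEvent(a, float(t)) for a, t in zip(actions, times)]
    records.append(RespondentRecord(
        id=f"p{i}", events=events, total_time=float(times[-1] + 0.1),
        group=group, covariates=np.empty(0)))
dataset = LogDataset(records, sorted({a for r in records for a in r.actions}),
                     [])

table = am.chi_square_scores(dataset)
print(f"{'action':<8} {'chi2':>8} {'W_correct':>10} {'W_incorrect':>12} rep?")
for row in table.rows:
    print(f"{row.action:<8} {row.chi2:>8.2f} {row.w_correct:>10.2f} "
          f"{row.w_incorrect:>12.2f} {row.correct_representative}")

keys = am.select_key_actions(table, strategy="elbow")
print(f"\nkey actions (elbow rule): {keys}")
print("these are the actions over-represented in the correct group with "
      "scores above the elbow of the ranking curve; 'start'/'submit' score "
      "zero because everyone uses them (ISF weight 0)")
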