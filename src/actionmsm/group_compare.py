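"""Posterior comparison of correct vs incorrect transition probabilities.

For every stored posterior draw, the embedded-chain matrix of each group is
computed and differenced (correct minus incorrect) over the action pairs
supported in both groups.  A pair's difference is called significant when
its 95% highest-posterior-density interval excludes zero; no multiplicity
correction is applied across pairs (each pair is judged by its own interval;
pass a smaller ``level`` complement to tighten).  Person speed is set to 1
and covariates cancel row-wise, so the comparison is purely between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_fit import PosteriorSamples, hpd_interval

__all__ = ["ComparisonResult", "transition_difference", "export_heatmap",
           "export_edge_list"]


@dataclass
class ComparisonResult:
    """Per-pair posterior summary of the group transition-probability gap.

    ``table`` has one row per pair supported in both groups: mean_diff
    (posterior mean of P_correct - P_incorrect), HPD bounds, significance
    flag and direction (+1 correct group faster, -1 incorrect, 0 not
    significant).  ``excluded`` lists pairs supported in exactly one group.
    """

    table: pd.DataFrame
    states: list[str]
    key_set: frozenset[str]
    covariate_setting: dict[str, float] = field(default_factory=dict)
    excluded: list[tuple[str, str, int]] = field(default_factory=list)
    level: float = 0.95


def _group_prob_draws(samples: PosteriorSamples, g: int) -> dict[tuple[str, str], np.ndarray]:
    """Per-draw embedded-chain probabilities for every supported pair of g."""
    flat = samples.draws.reshape(-1, len(samples.names))
    pairs = samples.index[("lam_pairs", g)]
    lam = flat[:, samples.index[("lam", g)]]  # (ndraws, ncells)
    if ("gamma2", g) in samples.index:
        g2 = flat[:, samples.index[("gamma2", g)]]
        kcol = np.array([l in samples.key_set for _, l in pairs])
        weights = lam * np.exp(np.outer(g2, kcol))
    else:
        weights = lam
    sidx = {s: i for i, s in enumerate(samples.states)}
    rows = np.array([sidx[m] for m, _ in pairs])
    denom = np.zeros((weights.shape[0], len(samples.states)))
    np.add.at(denom.T, rows, weights.T)
    probs = weights / denom[:, rows]
    return {pair: probs[:, k] for k, pair in enumerate(pairs)}


def transition_difference(samples: PosteriorSamples,
                          covariate_setting: dict[str, float] | None = None,
                          level: float = 0.95) -> ComparisonResult:
    """Posterior difference in transition probabilities, correct - incorrect.

    ``covariate_setting`` names covariate values for the evaluation point;
    under the multiplicative hazard these cancel within each row, so the
    result is independent of the setting (it is recorded for provenance).
    Pairs supported in only one group are excluded and listed separately.
    """
    if set(samples.groups) != {0, 1}:
        raise ValueError("both correctness groups are required for comparison")
    p0 = _group_prob_draws(samples, 0)
    p1 = _group_prob_draws(samples, 1)
    common = sorted(set(p0) & set(p1))
    excluded = ([(m, l, 0) for (m, l) in sorted(set(p0) - set(p1))]
                + [(m, l, 1) for (m, l) in sorted(set(p1) - set(p0))])
    rows = []
    for (m, l) in common:
        diff = p1[(m, l)] - p0[(m, l)]
        lo, hi = hpd_interval(diff, level)
        sig = not (lo <= 0.0 <= hi)
        rows.append({
            "from": m, "to": l,
            "mean_diff": float(diff.mean()),
            "hpd_lo": lo, "hpd_hi": hi,
            "significant": sig,
            "direction": (0 if not sig else (1 if diff.mean() > 0 else -1)),
            "from_is_key": m in samples.key_set,
            "to_is_key": l in samples.key_set,
        })
    table = pd.DataFrame(rows, columns=["from", "to", "mean_diff", "hpd_lo",
                                        "hpd_hi", "significant", "direction",
                                        "from_is_key", "to_is_key"])
    return ComparisonResult(table=table, states=list(samples.states),
                            key_set=samples.key_set,
                            covariate_setting=dict(covariate_setting or {}),
                            excluded=excluded, level=level)


def export_heatmap(result: ComparisonResult, path,
                   mask_path=None) -> pd.DataFrame:
    """Write the E x E signed-difference matrix as CSV (source rows,
    destination columns); non-significant cells are zero.  ``mask_path``
    additionally writes a 0/1 significance mask of the same shape."""
    states = result.states
    mat = pd.DataFrame(0.0, index=states, columns=states)
    mask = pd.DataFrame(0, index=states, columns=states)
    sig = result.table[result.table["significant"]]
    for m, l, d in zip(sig["from"], sig["to"], sig["mean_diff"]):
        mat.loc[m, l] = d
        mask.loc[m, l] = 1
    mat.to_csv(path, index_label="from")
    if mask_path is not None:
        mask.to_csv(mask_path, index_label="from")
    return mat


def export_edge_list(result: ComparisonResult, path) -> pd.DataFrame:
    """Write significant pairs as a directed edge list CSV.

    Columns: from, to, mean_diff, hpd_lo, hpd_hi, direction, from_is_key,
    to_is_key; sorted by absolute difference, largest first.
    """
    edges = result.table[result.table["significant"]].copy()
    edges = edges.sort_values("mean_diff", key=np.abs, ascending=False,
                              kind="stable")
    edges = edges.drop(columns=["significant"])
    edges.to_csv(path, index=False)
    return edges
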