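"""Key-action extraction via TF-ISF-weighted chi-square scores.

Actions that discriminate correct from incorrect responders are found by a
text-mining analogy: each action is a "term", each respondent's sequence a
"document".  Ubiquitous actions are down-weighted by the inverse sequence
frequency (ISF), per-respondent occurrence counts give the term frequency
(TF), and the weighted frequencies are cross-tabulated against correctness
in a 2x2 table whose chi-square score ranks the actions.  Actions over-
represented in the correct group and above an elbow threshold on the
descending score curve are the "key actions".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log_io import LogDataset, RespondentRecord

__all__ = [
    "ScoreRow",
    "ScoreTable",
    "inverse_sequence_frequency",
    "term_frequency",
    "weighted_frequencies",
    "chi_square_scores",
    "select_key_actions",
]


@dataclass(frozen=True)
class ScoreRow:
    action: str
    isf: float
    w_correct: float
    w_incorrect: float
    chi2: float
    correct_representative: bool


@dataclass
class ScoreTable:
    """Chi-square score table, rows sorted by score descending.

    ``len_correct`` / ``len_incorrect`` are the summed weighted frequencies
    of the two groups (the column margins of every action's 2x2 table).
    """

    rows: list[ScoreRow]
    len_correct: float
    len_incorrect: float
    key_actions: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        df["selected"] = df["action"].isin(self.key_actions)
        return df


def inverse_sequence_frequency(dataset: LogDataset,
                               denominator: str = "sequences") -> dict[str, float]:
    """ISF_i = ln(N / n_i) per observed action.

    ``n_i`` counts the sequences containing action i at least once
    (``denominator="sequences"``, the document-frequency reading); the
    alternative ``"occurrences"`` uses the total occurrence count.  Actions
    never observed are absent from the map.
    """
    n = dataset.n_respondents
    if n == 0:
        raise ValueError("empty dataset")
    counts: Counter[str] = Counter()
    for rec in dataset.records:
        if denominator == "sequences":
            counts.update(set(rec.actions))
        elif denominator == "occurrences":
            counts.update(rec.actions)
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
    return {a: math.log(n / c) for a, c in counts.items()}


def term_frequency(record: RespondentRecord) -> dict[str, int]:
    """TF_ij: occurrence count of each action in one respondent's sequence."""
    return dict(Counter(record.actions))


def weighted_frequencies(dataset: LogDataset,
                         denominator: str = "sequences",
                         ) -> tuple[dict[str, float], dict[str, float], float, float]:
    """Per-action weighted frequencies W_ic, W_iw and the group totals.

    w_ij = TF_ij * ISF_i, summed over respondents of each group.  Both groups
    must be represented.
    """
    groups = dataset.groups()
    if len(set(groups.tolist())) < 2:
        raise ValueError("single-group dataset: both correct and incorrect "
                         "respondents are required")
    isf = inverse_sequence_frequency(dataset, denominator)
    w_c: dict[str, float] = {a: 0.0 for a in isf}
    w_w: dict[str, float] = {a: 0.0 for a in isf}
    for rec in dataset.records:
        target = w_c if rec.group == 1 else w_w
        for action, tf in term_frequency(rec).items():
            target[action] += tf * isf[action]
    return w_c, w_w, sum(w_c.values()), sum(w_w.values())


def _chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square for a 2x2 table of (possibly non-integer) counts.

    No continuity correction.  A zero row or column margin makes the score 0
    (degenerate table carries no association evidence).
    """
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected == 0):
        return 0.0
    return float(((table - expected) ** 2 / expected).sum())


def chi_square_scores(dataset: LogDataset,
                      denominator: str = "sequences") -> ScoreTable:
    """Score every observed action by its weighted 2x2 chi-square statistic.

    For action i the table is ``[[W_ic, W_iw], [len_c - W_ic, len_w - W_iw]]``.
    ``correct_representative`` is True when the action's weighted share in the
    correct group exceeds its share in the incorrect group (the direction
    rule); ties in the ranking are broken alphabetically.
    """
    w_c, w_w, len_c, len_w = weighted_frequencies(dataset, denominator)
    if len_c <= 0 or len_w <= 0:
        raise ValueError("a group's total weighted frequency is zero")
    isf = inverse_sequence_frequency(dataset, denominator)
    rows = []
    for action in isf:
        wc, ww = w_c[action], w_w[action]
        chi2 = _chi2_2x2([[wc, ww], [len_c - wc, len_w - ww]])
        rows.append(ScoreRow(
            action=action, isf=isf[action], w_correct=wc, w_incorrect=ww,
            chi2=chi2,
            correct_representative=bool(wc / len_c > ww / len_w)))
    rows.sort(key=lambda r: (-r.chi2, r.action))
    return ScoreTable(rows=rows, len_correct=len_c, len_incorrect=len_w)


def _elbow_rank(scores: np.ndarray) -> int:
    """Index (0-based) of the elbow of a descending score curve.

    The elbow maximizes the perpendicular distance from (rank, score) to the
    chord joining the first and last points; first maximum wins on ties.
    """
    n = len(scores)
    if n < 2:
        raise ValueError("elbow undefined for fewer than two actions; "
                         "use top_k or min_score")
    r = np.arange(1, n + 1, dtype=float)
    y = scores.astype(float)
    dx, dy = n - 1.0, y[-1] - y[0]
    norm = math.hypot(dx, dy)
    if norm == 0 or np.allclose(y, y[0]):
        raise ValueError("all scores equal: elbow undefined; "
                         "use top_k or min_score")
    dist = np.abs(dy * (r - 1.0) - dx * (y - y[0])) / norm
    return int(np.argmax(dist))


def select_key_actions(table: ScoreTable, strategy: str = "elbow",
                       k: int | None = None,
                       min_score: float | None = None) -> list[str]:
    """Select key actions from a score table, ordered by score descending.

    Candidates are the correct-representative actions.  The default ``elbow``
    strategy keeps candidates whose score is strictly greater than the score
    at the elbow of the descending curve (the elbow action itself is
    excluded).  ``top_k`` and ``min_score`` are explicit overrides.
    """
    if not table.rows:
        raise ValueError("empty score table")
    candidates = [r for r in table.rows if r.correct_representative]
    if strategy == "elbow":
        scores = np.array([r.chi2 for r in table.rows])
        elbow = _elbow_rank(scores)
        threshold = table.rows[elbow].chi2
        selected = [r.action for r in candidates if r.chi2 > threshold]
    elif strategy == "top_k":
        if k is None or k < 0:
            raise ValueError("top_k strategy requires k >= 0")
        selected = [r.action for r in candidates[:k]]
    elif strategy == "min_score":
        if min_score is None:
            raise ValueError("min_score strategy requires a threshold")
        selected = [r.action for r in candidates if r.chi2 >= min_score]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    table.key_actions = selected
    return selected
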