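"""Data model, validation and file I/O for timestamped action-sequence logs.

An event log records one row per user action: who acted, which action, and
when (in minutes since item onset).  A companion respondent table carries the
binary correctness label, the total solution time and any numeric covariates.
Covariates are consumed as-is; any standardization is the caller's
responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ActionEvent",
    "RespondentRecord",
    "LogDataset",
    "read_log",
    "write_log",
    "collapse_repeats",
]


@dataclass(frozen=True)
class ActionEvent:
    """A single logged action occurrence.

    Parameters
    ----------
    action : str
        Action label; must belong to the dataset vocabulary.
    time : float
        Occurrence time in minutes since item onset (non-negative).
    """

    action: str
    time: float


@dataclass
class RespondentRecord:
    """One respondent's ordered action sequence plus metadata.

    ``group`` is the correctness indicator (1 = correct, 0 = incorrect);
    ``total_time`` is the total solution time in minutes and must be at least
    the time of the last event (the trailing interval is the right-censored
    sojourn in the final state).
    """

    id: str
    events: list[ActionEvent]
    total_time: float
    group: int
    covariates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def actions(self) -> list[str]:
        return [e.action for e in self.events]

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)


@dataclass
class LogDataset:
    """A validated collection of respondent records with a shared vocabulary.

    ``vocabulary`` fixes the state ordering used everywhere downstream
    (transition matrices, heatmap exports); by default it is the sorted union
    of observed action labels.
    """

    records: list[RespondentRecord]
    vocabulary: list[str]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return len(self.records)

    @property
    def n_actions(self) -> int:
        return len(self.vocabulary)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records], dtype=int)

    def covariate_matrix(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, self.n_covariates))
        return np.vstack([r.covariates.reshape(1, -1) if r.covariates.size
                          else np.empty((1, 0)) for r in self.records])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.records:
            raise ValueError("no events: dataset contains no respondents")
        vocab = set(self.vocabulary)
        p = self.n_covariates
        seen_ids = set()
        for rec in self.records:
            if rec.id in seen_ids:
                raise ValueError(f"duplicate respondent id {rec.id!r}")
            seen_ids.add(rec.id)
            if not rec.events:
                raise ValueError(f"respondent {rec.id!r} has no events")
            if rec.group not in (0, 1):
                raise ValueError(
                    f"respondent {rec.id!r}: group must be 0 or 1, got {rec.group!r}")
            if rec.covariates.size != p:
                raise ValueError(
                    f"respondent {rec.id!r}: expected {p} covariates, "
                    f"got {rec.covariates.size}")
            prev = -np.inf
            for ev in rec.events:
                if ev.time < 0:
                    raise ValueError(
                        f"respondent {rec.id!r}: negative time {ev.time}")
                if ev.time < prev:
                    raise ValueError(
                        f"respondent {rec.id!r}: non-monotone event times")
                prev = ev.time
                if ev.action not in vocab:
                    raise ValueError(
                        f"respondent {rec.id!r}: action {ev.action!r} "
                        "not in vocabulary")
            if rec.total_time < rec.events[-1].time:
                raise ValueError(
                    f"respondent {rec.id!r}: total_time {rec.total_time} "
                    f"precedes last event at {rec.events[-1].time}")

    # -- frame conversion ------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (events, respondents) DataFrames in the on-disk layout."""
        ev_rows = [
            {"respondent_id": rec.id, "action": ev.action, "time": ev.time}
            for rec in self.records for ev in rec.events
        ]
        events = pd.DataFrame(ev_rows, columns=["respondent_id", "action", "time"])
        resp_rows = []
        for rec in self.records:
            row = {"respondent_id": rec.id, "group": rec.group,
                   "total_time": rec.total_time}
            for name, val in zip(self.covariate_names, rec.covariates):
                row[name] = val
            resp_rows.append(row)
        respondents = pd.DataFrame(
            resp_rows,
            columns=["respondent_id", "group", "total_time", *self.covariate_names])
        return events, respondents


def _dataset_from_frames(events: pd.DataFrame, respondents: pd.DataFrame,
                         vocabulary: list[str] | None = None) -> LogDataset:
    required_ev = {"respondent_id", "action", "time"}
    if not required_ev.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required_ev)}")
    required_rs = {"respondent_id", "group", "total_time"}
    if not required_rs.issubset(respondents.columns):
        raise ValueError(f"respondents table must have columns {sorted(required_rs)}")
    if events.empty:
        raise ValueError("no events")

    covariate_names = [c for c in respondents.columns if c not in required_rs]
    events = events.copy()
    events["respondent_id"] = events["respondent_id"].astype(str)
    respondents = respondents.copy()
    respondents["respondent_id"] = respondents["respondent_id"].astype(str)

    ev_ids = set(events["respondent_id"])
    rs_ids = set(respondents["respondent_id"])
    if ev_ids - rs_ids:
        missing = sorted(ev_ids - rs_ids)[:5]
        raise ValueError(f"respondents missing from respondent table: {missing}")
    if rs_ids - ev_ids:
        missing = sorted(rs_ids - ev_ids)[:5]
        raise ValueError(f"respondents with no events: {missing}")

    # stable sort keeps tied timestamps in file order
    events = events.sort_values(["respondent_id", "time"], kind="stable")

    grouped = {rid: grp for rid, grp in events.groupby("respondent_id", sort=False)}
    records = []
    for row in respondents.itertuples(index=False):
        rid = row.respondent_id
        grp = grouped[rid]
        evs = [ActionEvent(str(a), float(t))
               for a, t in zip(grp["action"], grp["time"])]
        covs = np.array([getattr(row, c) for c in covariate_names], dtype=float)
        records.append(RespondentRecord(
            id=rid, events=evs, total_time=float(row.total_time),
            group=int(row.group), covariates=covs))

    if vocabulary is None:
        vocabulary = sorted({e.action for r in records for e in r.events})
    return LogDataset(records=records, vocabulary=list(vocabulary),
                      covariate_names=covariate_names)


def read_log(events_path, respondents_path, vocabulary_path=None) -> LogDataset:
    """Read a long-format events CSV and a respondent table into a dataset.

    The events file has columns ``respondent_id,action,time`` (time in decimal
    minutes); the respondent file ``respondent_id,group,total_time`` plus any
    number of covariate columns.  An optional vocabulary file (one label per
    line) fixes the state ordering; otherwise the sorted union of observed
    actions is used.
    """
    # keep_default_na: action labels like "NA" are real labels, not missing
    events = pd.read_csv(events_path, dtype={"respondent_id": str, "action": str},
                         float_precision="round_trip", keep_default_na=False)
    respondents = pd.read_csv(respondents_path, dtype={"respondent_id": str},
                              float_precision="round_trip")
    vocabulary = None
    if vocabulary_path is not None:
        with open(vocabulary_path, encoding="utf-8") as fh:
            vocabulary = [line.rstrip("\n") for line in fh if line.strip()]
    ds = _dataset_from_frames(events, respondents, vocabulary)
    if vocabulary is not None:
        observed = {e.action for r in ds.records for e in r.events}
        unknown = observed - set(vocabulary)
        if unknown:
            raise ValueError(f"actions not in vocabulary file: {sorted(unknown)[:5]}")
    return ds


def write_log(dataset: LogDataset, events_path, respondents_path,
              vocabulary_path=None) -> None:
    """Write a dataset back to the CSV layout accepted by :func:`read_log`.

    Round-trips exactly: times are written with shortest round-trippable
    float representation and labels byte-exact (UTF-8).
    """
    events, respondents = dataset.to_frames()
    # repr-based formatting round-trips float64 exactly
    events["time"] = [repr(float(t)) for t in events["time"]]
    events.to_csv(events_path, index=False)
    respondents.to_csv(respondents_path, index=False)
    if vocabulary_path is not None:
        with open(vocabulary_path, "w", encoding="utf-8") as fh:
            for label in dataset.vocabulary:
                fh.write(label + "\n")


def collapse_repeats(dataset: LogDataset, enabled: bool = True) -> LogDataset:
    """Merge consecutive identical actions within each respondent.

    The first timestamp of each run is kept.  With ``enabled=False`` this is
    the identity, so callers can thread a flag through a pipeline.  Collapsing
    removes observable self-transitions (m -> m), which is the classical
    continuous-time-Markov reading of the log.
    """
    if not enabled:
        return dataset
    new_records = []
    for rec in dataset.records:
        kept: list[ActionEvent] = []
        for ev in rec.events:
            if kept and kept[-1].action == ev.action:
                continue
            kept.append(ev)
        new_records.append(replace(rec, events=kept))
    return LogDataset(records=new_records, vocabulary=list(dataset.vocabulary),
                      covariate_names=list(dataset.covariate_names))
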