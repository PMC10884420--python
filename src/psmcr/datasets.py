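"""Domain containers and file I/O for competing-risks and multistate survival data.

The central container is :class:`CompetingRisksDataset`: one row per subject
with an observed time, a status code (0 = right-censored, 1 = death from
cause 1, 2 = death from cause 2), a numeric covariate matrix, and an optional
group label (e.g. gender). Multistate follow-up (the four-state
LRC -> FP -> DP -> Death topology) is handled in "wide" form (one row per
subject with per-state event times) and converted to mstate-style "long"
records, one row per at-risk transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompetingRisksDataset",
    "MultistateRecord",
    "ALLOWED_TRANSITIONS",
    "read_dataset",
    "write_dataset",
    "to_long_transitions",
    "wide_to_competing_risks",
]

#: Forward-only transitions of the four-state model
#: (1 = loco-regional control, 2 = first progression, 3 = distant
#: progression, 4 = death). Death without progression (1 -> 4) is competing
#: risk 2; death after progression (2 -> 4 or 3 -> 4) is competing risk 1.
ALLOWED_TRANSITIONS = ((1, 2), (1, 4), (2, 3), (2, 4), (3, 4))

STATE_NAMES = {1: "LRC", 2: "FP", 3: "DP", 4: "Death"}


class ValidationError(ValueError):
    """Raised when input data violate a dataset invariant."""


@dataclass(frozen=True)
class CompetingRisksDataset:
    """Subject-level competing-risks survival data.

    Parameters
    ----------
    ids : array of str
        Subject identifiers.
    times : array of float
        Observed times (event or censoring), all > 0.
    statuses : array of int
        0 = censored, 1 = cause-1 event, 2 = cause-2 event.
    covariates : pandas.DataFrame
        n x m numeric covariate matrix with unique column names, no NaN.
    group : array of str, optional
        Categorical label per subject (e.g. gender).
    censoring_time : float, optional
        Administrative censoring cutoff; every censored subject must have
        time <= censoring_time when set.
    """

    ids: np.ndarray
    times: np.ndarray
    statuses: np.ndarray
    covariates: pd.DataFrame
    group: np.ndarray | None = None
    censoring_time: float | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=str)
        times = np.asarray(self.times, dtype=float)
        statuses = np.asarray(self.statuses)
        cov = self.covariates
        if not isinstance(cov, pd.DataFrame):
            cov = pd.DataFrame(np.asarray(cov, dtype=float))
            cov.columns = [f"x{j + 1}" for j in range(cov.shape[1])]
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "statuses", statuses.astype(int))
        object.__setattr__(self, "covariates", cov.reset_index(drop=True))
        if self.group is not None:
            object.__setattr__(self, "group", np.asarray(self.group, dtype=str))
        self._validate(statuses)

    def _validate(self, raw_statuses: np.ndarray) -> None:
        n = len(self.times)
        if n < 1:
            raise ValidationError("dataset must contain at least one subject")
        for name, arr in (("ids", self.ids), ("statuses", self.statuses)):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != times length {n}")
        if self.group is not None and len(self.group) != n:
            raise ValidationError("group length does not match number of subjects")
        if len(self.covariates) != n:
            raise ValidationError("covariate matrix row count does not match times")
        if self.covariates.shape[1] < 1:
            raise ValidationError("at least one covariate column is required")
        if len(set(self.covariates.columns)) != self.covariates.shape[1]:
            raise ValidationError("covariate column names must be unique")
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            bad = int(np.flatnonzero(~(np.isfinite(self.times) & (self.times > 0)))[0])
            raise ValidationError(f"non-positive or non-finite time in row {bad}")
        bad_status = ~np.isin(np.asarray(raw_statuses), (0, 1, 2))
        if np.any(bad_status):
            row = int(np.flatnonzero(bad_status)[0])
            raise ValidationError(
                f"status {np.asarray(raw_statuses)[row]!r} in row {row} is not one of 0, 1, 2"
            )
        if self.covariates.isna().any().any():
            col = self.covariates.columns[self.covariates.isna().any()][0]
            raise ValidationError(f"missing covariate values in column {col!r}")
        if not all(np.issubdtype(d, np.number) for d in self.covariates.dtypes):
            raise ValidationError("covariate columns must be numeric")
        if self.censoring_time is not None:
            censored = self.statuses == 0
            if np.any(self.times[censored] > self.censoring_time + 1e-12):
                row = int(np.flatnonzero(censored & (self.times > self.censoring_time))[0])
                raise ValidationError(
                    f"censored subject in row {row} has time beyond the "
                    f"administrative censoring time {self.censoring_time}"
                )

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def X(self) -> np.ndarray:
        """Covariate matrix as a float ndarray (n x m)."""
        return self.covariates.to_numpy(dtype=float)

    def n_events(self, cause: int) -> int:
        return int(np.sum(self.statuses == cause))

    def with_statuses(self, statuses: np.ndarray) -> "CompetingRisksDataset":
        """Copy of the dataset with a replaced status vector (times untouched)."""
        return replace(self, statuses=np.asarray(statuses, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form: id, time, status, [group], covariates."""
        data: dict[str, np.ndarray | pd.Series] = {
            "id": self.ids,
            "time": self.times,
            "status": self.statuses,
        }
        if self.group is not None:
            data["group"] = self.group
        frame = pd.DataFrame(data)
        return pd.concat([frame, self.covariates.reset_index(drop=True)], axis=1)


@dataclass(frozen=True)
class MultistateRecord:
    """One at-risk transition interval in mstate-style long format."""

    id: str
    from_state: int
    to_state: int
    entry_time: float
    exit_time: float
    event: int
    cause: int | None = None

    def __post_init__(self) -> None:
        if (self.from_state, self.to_state) not in ALLOWED_TRANSITIONS:
            raise ValidationError(
                f"transition {self.from_state}->{self.to_state} is not allowed "
                f"by the forward-only topology"
            )
        if self.exit_time < self.entry_time:
            raise ValidationError("exit_time must be >= entry_time")
        if self.event not in (0, 1):
            raise ValidationError("event flag must be 0 or 1")


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str | Sequence[str]] | None = None,
    censoring_time: float | None = None,
) -> CompetingRisksDataset:
    """Read a subject-level CSV into a :class:`CompetingRisksDataset`.

    ``schema`` maps roles to column names: keys ``id``, ``time``, ``status``,
    optional ``group``, and optional ``covariates`` (list). By default the
    columns are taken literally as id, time, status, optional group, and all
    remaining columns as covariates.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    schema = dict(schema or {})
    id_col = str(schema.get("id", "id"))
    time_col = str(schema.get("time", "time"))
    status_col = str(schema.get("status", "status"))
    group_col = schema.get("group", "group" if "group" in frame.columns else None)
    for col in (id_col, time_col, status_col):
        if col not in frame.columns:
            raise ValidationError(f"required column {col!r} missing from {path}")
    if group_col is not None and group_col not in frame.columns:
        raise ValidationError(f"group column {group_col!r} missing from {path}")
    cov_cols = schema.get("covariates")
    if cov_cols is None:
        reserved = {id_col, time_col, status_col, group_col}
        cov_cols = [c for c in frame.columns if c not in reserved]
    missing = [c for c in cov_cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"covariate columns {missing} missing from {path}")
    return CompetingRisksDataset(
        ids=frame[id_col].astype(str).to_numpy(),
        times=frame[time_col].to_numpy(dtype=float),
        statuses=frame[status_col].to_numpy(),
        covariates=frame[list(cov_cols)].astype(float),
        group=frame[group_col].astype(str).to_numpy() if group_col else None,
        censoring_time=censoring_time,
    )


def write_dataset(dataset: CompetingRisksDataset, path: str | Path) -> None:
    """Write a dataset as CSV in canonical column order.

    Floats use the shortest round-trip representation, so a write/read
    cycle reproduces every numeric value exactly.
    """
    dataset.to_frame().to_csv(path, index=False)


def _check_order(sid: str, label_times: list[tuple[str, float]]) -> None:
    seq = [(name, t) for name, t in label_times if t is not None and not np.isnan(t)]
    for (name_a, a), (name_b, b) in zip(seq, seq[1:]):
        if b < a:
            raise ValidationError(
                f"subject {sid}: {name_b} time {b} precedes {name_a} time {a}"
            )


def to_long_transitions(wide: pd.DataFrame) -> pd.DataFrame:
    """Expand a wide four-state table into mstate-style long format.

    ``wide`` has one row per subject with columns ``id``, ``lrc_time``
    (entry into state 1), optional ``fp_time``, ``dp_time``, ``death_time``,
    ``cause``, and ``last_followup``; any further columns (covariates,
    gender, ...) are carried over onto every long row.

    Each subject contributes one row per at-risk transition: while occupying
    state i, a row for every allowed i -> j with ``event`` = 1 for the
    realized transition and 0 for the others, censored at the exit from the
    state (or at last follow-up). Transitions into death carry ``cause``:
    2 for direct death (1 -> 4), 1 for death after progression.
    """
    extra_cols = [
        c
        for c in wide.columns
        if c not in {"id", "lrc_time", "fp_time", "dp_time", "death_time", "cause", "last_followup"}
    ]
    rows: list[dict] = []
    for _, rec in wide.iterrows():
        sid = str(rec["id"])
        start = float(rec.get("lrc_time", 0.0) or 0.0)
        fp = _opt(rec, "fp_time")
        dp = _opt(rec, "dp_time")
        death = _opt(rec, "death_time")
        last = float(rec["last_followup"])
        _check_order(
            sid,
            [("lrc", start), ("fp", fp), ("dp", dp), ("death", death), ("last_followup", last)],
        )
        if dp is not None and fp is None:
            raise ValidationError(f"subject {sid}: distant progression without first progression")
        extras = {c: rec[c] for c in extra_cols}

        def add(frm: int, to: int, entry: float, exit_: float, event: int, cause: int | None) -> None:
            rows.append(
                dict(
                    id=sid,
                    from_state=frm,
                    to_state=to,
                    entry_time=entry,
                    exit_time=exit_,
                    event=event,
                    cause=cause,
                    **extras,
                )
            )

        # state 1: at risk for 1->2 and 1->4
        exit1 = fp if fp is not None else (death if death is not None else last)
        add(1, 2, start, exit1, int(fp is not None), None)
        died_direct = death is not None and fp is None
        add(1, 4, start, exit1, int(died_direct), 2 if died_direct else None)
        if fp is not None:
            # state 2: at risk for 2->3 and 2->4
            exit2 = dp if dp is not None else (death if death is not None else last)
            add(2, 3, fp, exit2, int(dp is not None), None)
            died_from_fp = death is not None and dp is None
            add(2, 4, fp, exit2, int(died_from_fp), 1 if died_from_fp else None)
            if dp is not None:
                exit3 = death if death is not None else last
                add(3, 4, dp, exit3, int(death is not None), 1 if death is not None else None)
    long = pd.DataFrame(rows)
    long["cause"] = long["cause"].astype("Int64")
    return long


def _opt(rec: pd.Series, key: str) -> float | None:
    val = rec.get(key)
    if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
        return None
    return float(val)


def wide_to_competing_risks(
    wide: pd.DataFrame,
    covariate_cols: Sequence[str],
    group_col: str | None = None,
) -> CompetingRisksDataset:
    """Collapse a wide four-state table to flat competing-risks rows.

    Time is the death time for deceased subjects and the last follow-up
    otherwise; status is the competing-event cause (1 = death after
    progression, 2 = direct death) or 0 for censored.
    """
    death = wide["death_time"]
    dead = death.notna()
    times = np.where(dead, death, wide["last_followup"]).astype(float)
    statuses = np.where(dead, wide["cause"].fillna(0), 0).astype(int)
    return CompetingRisksDataset(
        ids=wide["id"].astype(str).to_numpy(),
        times=times,
        statuses=statuses,
        covariates=wide[list(covariate_cols)].astype(float),
        group=wide[group_col].astype(str).to_numpy() if group_col else None,
    )
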