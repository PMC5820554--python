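"""Domain types and delimited-text I/O for paired time-to-progression data.

A trial record consists of, per patient, the time to progression on the
previous treatment line (``ttp1``, always observed by design: patients enter
the study at their first progression), the time to progression on the current
line (``ttp2``), and an event indicator for ``ttp2`` (1 = progression
observed, 0 = right-censored at ``ttp2``). Times are positive reals; months
are the conventional unit but every estimator in this package is invariant to
a common rescaling of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedTrialData",
    "GMIObservation",
    "GMISample",
    "EstimateWithCI",
    "TrialSchemaError",
    "TrialValidationError",
    "read_trial",
    "write_trial",
    "to_gmi",
]

#: canonical column names of the delimited-text format
COLUMNS = ("ttp1", "ttp2", "event2")


class TrialSchemaError(ValueError):
    """A required column is missing from an input file."""


class TrialValidationError(ValueError):
    """A value violates the domain invariants (nonpositive time, bad flag)."""


@dataclass(frozen=True)
class PairedTrialData:
    """Per-patient paired failure times with censoring status on the second.

    Parameters
    ----------
    ttp1 : array of positive floats
        Time to progression on the previous treatment line; always observed.
    ttp2 : array of positive floats
        Time to progression (or censoring time) on the current line.
    event2 : integer array of 0/1
        1 if the second progression was observed, 0 if right-censored.
    """

    ttp1: np.ndarray
    ttp2: np.ndarray
    event2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ttp1", np.asarray(self.ttp1, dtype=float))
        object.__setattr__(self, "ttp2", np.asarray(self.ttp2, dtype=float))
        object.__setattr__(self, "event2", np.asarray(self.event2, dtype=int))
        if not (self.ttp1.ndim == self.ttp2.ndim == self.event2.ndim == 1):
            raise TrialValidationError("ttp1, ttp2 and event2 must be 1-d sequences")
        n = len(self.ttp1)
        if n < 1:
            raise TrialValidationError("at least one patient is required")
        if len(self.ttp2) != n or len(self.event2) != n:
            raise TrialValidationError(
                f"length mismatch: ttp1 has {n}, ttp2 has {len(self.ttp2)}, "
                f"event2 has {len(self.event2)}"
            )
        for name, arr in (("ttp1", self.ttp1), ("ttp2", self.ttp2)):
            bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
            if bad.size:
                raise TrialValidationError(
                    f"{name} must be positive and finite; offending row {bad[0]} "
                    f"(value {arr[bad[0]]!r})"
                )
        bad = np.flatnonzero(~np.isin(self.event2, (0, 1)))
        if bad.size:
            raise TrialValidationError(
                f"event2 must be 0 or 1; offending row {bad[0]} "
                f"(value {self.event2[bad[0]]!r})"
            )

    @property
    def n(self) -> int:
        """Number of patients."""
        return len(self.ttp1)

    @property
    def n_events(self) -> int:
        """Number of observed second progressions."""
        return int(self.event2.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ttp1": self.ttp1, "ttp2": self.ttp2, "event2": self.event2}
        )


@dataclass(frozen=True)
class GMIObservation:
    """One patient's growth modulation index with its censoring status.

    ``ratio`` is TTP2/TTP1; ``event`` is 1 when the ratio is observed exactly
    and 0 when it is only a lower bound (TTP2 right-censored).
    """

    ratio: float
    event: int


@dataclass(frozen=True)
class GMISample:
    """A trial recoded on the GMI scale: ratios with event flags.

    Behaves as a sequence of :class:`GMIObservation`; the raw arrays are the
    working representation for the estimators.
    """

    ratio: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", np.asarray(self.ratio, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if len(self.ratio) != len(self.event):
            raise TrialValidationError("ratio and event must have equal length")
        if np.any(~(self.ratio > 0)):
            raise TrialValidationError("all ratios must be positive")
        if np.any(~np.isin(self.event, (0, 1))):
            raise TrialValidationError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.ratio)

    def __getitem__(self, i: int) -> GMIObservation:
        return GMIObservation(float(self.ratio[i]), int(self.event[i]))

    def __iter__(self) -> Iterator[GMIObservation]:
        for i in range(len(self)):
            yield self[i]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class EstimateWithCI:
    """An estimate of S_GMI(delta) = P(TTP2/TTP1 > delta) with a Wald CI."""

    method: str
    delta: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise TrialValidationError(
                f"inconsistent estimate/CI: {self.estimate} not inside "
                f"[{self.ci_low}, {self.ci_high}] within [0, 1]"
            )

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "delta": self.delta,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n": self.n,
            "n_events": self.n_events,
        }


def read_trial(
    path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> PairedTrialData:
    """Read a paired-trial file (CSV by default, TSV accepted).

    Parameters
    ----------
    path : str or path-like
        Delimited text file with a header row, UTF-8 encoded.
    dialect : mapping, optional
        Maps canonical names (``ttp1``, ``ttp2``, ``event2``) to the column
        names actually used in the file, e.g. ``{"event2": "progressed"}``.
    delimiter : str, optional
        Explicit field delimiter; inferred (comma or tab) when omitted.
    """
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    # round_trip: exact re-parsing of shortest-repr floats
    df = pd.read_csv(
        path, sep=delimiter, encoding="utf-8", float_precision="round_trip"
    )
    names = {c: c for c in COLUMNS}
    if dialect:
        names.update({k: v for k, v in dialect.items() if k in COLUMNS})
    missing = [src for src in names.values() if src not in df.columns]
    if missing:
        raise TrialSchemaError(
            f"missing column(s) {missing} in {path}; available: {list(df.columns)}"
        )
    cols = {}
    for canon, src in names.items():
        try:
            cols[canon] = pd.to_numeric(df[src], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            raise TrialValidationError(
                f"column {src!r} could not be parsed as numeric: {exc}"
            ) from exc
    return PairedTrialData(cols["ttp1"], cols["ttp2"], cols["event2"])


def write_trial(data: PairedTrialData, path, delimiter: str = ",") -> None:
    """Write a trial in the canonical delimited-text format (full precision)."""
    # repr of a Python float is the shortest exactly round-tripping decimal form
    data.to_frame().to_csv(
        path, sep=delimiter, index=False, float_format=lambda x: repr(float(x))
    )


def to_gmi(data: PairedTrialData) -> GMISample:
    """Recode paired times as ratio observations GMI_i = ttp2_i / ttp1_i.

    A censored ttp2 yields a censored ratio (the true GMI exceeds the
    recorded value). Threshold comparisons are left to the estimators.
    """
    return GMISample(data.ttp2 / data.ttp1, data.event2.copy())


def estimates_table(estimates: Sequence[EstimateWithCI]) -> str:
    """Human-readable fixed-width table of estimates."""
    header = (
        f"{'method':<15}{'delta':>7}{'estimate':>10}{'se':>8}"
        f"{'ci_low':>8}{'ci_high':>9}{'level':>7}{'n':>6}{'events':>8}"
    )
    lines = [header, "-" * len(header)]
    for e in estimates:
        lines.append(
            f"{e.method:<15}{e.delta:>7.3g}{e.estimate:>10.4f}{e.se:>8.4f}"
            f"{e.ci_low:>8.4f}{e.ci_high:>9.4f}{e.level:>7.3g}{e.n:>6d}"
            f"{e.n_events:>8d}"
        )
    return "\n".join(lines)
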