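"""Encounter records and capture histories for dual-channel mark-resight surveys.

A survey yields long-format encounter records: one row per individual x
occasion x detection channel.  Two channels are distinguished: conventional
visual resighting (``CV``, naked-eye observation of the mark) and high-speed
video resighting (``HSV``, marks read later from slowed-down footage).  This
module validates the records, collapses them into binary capture-history
matrices (either CV alone or the union CV+HSV), and summarizes resighting
counts.

An individual seen by both channels on the same day contributes a single
detection: histories are built by set-union over (individual, occasion),
which makes the same-day duplicate rule order-independent.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("resight")


class Channel(str, enum.Enum):
    """Detection channel: conventional visual or high-speed video."""

    CV = "CV"
    HSV = "HSV"


class Event(str, enum.Enum):
    """Encounter type: the single physical marking capture, or a resight."""

    initial_capture = "initial_capture"
    resight = "resight"


@dataclass(frozen=True)
class EncounterRecord:
    """One detection event of a marked individual.

    Parameters
    ----------
    individual_id
        Stable identifier (the code written on the wing).
    occasion
        1-based survey-day index.
    channel
        ``Channel.CV`` or ``Channel.HSV``.
    event
        ``initial_capture`` (the physical marking capture, always CV) or
        ``resight``.
    """

    individual_id: str
    occasion: int
    channel: Channel
    event: Event

    def __post_init__(self) -> None:
        if self.occasion < 1:
            raise ValueError(f"occasion must be >= 1, got {self.occasion}")
        if self.event is Event.initial_capture and self.channel is not Channel.CV:
            raise ValueError(
                f"initial_capture is a physical capture and must use channel CV "
                f"(individual {self.individual_id!r}, occasion {self.occasion})"
            )


@dataclass
class CaptureHistory:
    """Binary detection matrix for n individuals over T occasions.

    ``Y[i, t]`` is 1 iff individual ``i`` was encountered on occasion ``t + 1``
    (columns are 0-based, occasions 1-based).  ``e[i]`` is the 1-based first
    capture occasion; by construction ``Y[i, e[i]-1] == 1`` and all earlier
    entries are 0.
    """

    individual_ids: list[str]
    T: int
    Y: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        self.e = np.asarray(self.e, dtype=np.int64)
        if self.Y.shape != (len(self.individual_ids), self.T):
            raise ValueError(
                f"Y has shape {self.Y.shape}, expected "
                f"({len(self.individual_ids)}, {self.T})"
            )
        if self.e.shape != (len(self.individual_ids),):
            raise ValueError("e must have one entry per individual")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def last_detection(self) -> np.ndarray:
        """1-based occasion of each individual's last detection."""
        occ = np.arange(1, self.T + 1)
        return (self.Y * occ).max(axis=1)

    def to_records(self, channel: Channel = Channel.CV) -> list[EncounterRecord]:
        """Emit the encounter records this matrix encodes (single channel)."""
        out: list[EncounterRecord] = []
        for i, iid in enumerate(self.individual_ids):
            for t in np.nonzero(self.Y[i])[0] + 1:
                event = Event.initial_capture if t == self.e[i] else Event.resight
                out.append(EncounterRecord(iid, int(t), channel, event))
        return out


@dataclass
class CovariateTable:
    """Per-individual covariates: sex and hind-wing length.

    Wing length is in mm (field-measured to 0.01 mm with a caliper).
    ``sex`` uses 'F'/'M'.  ``first_occasion`` is the marking day and must
    agree with the capture history's ``e``.
    """

    table: pd.DataFrame

    REQUIRED = ("individual_id", "sex", "wing_length", "first_occasion")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if self.table["individual_id"].duplicated().any():
            dup = self.table.loc[
                self.table["individual_id"].duplicated(), "individual_id"
            ].tolist()
            raise ValueError(f"duplicate covariate rows for individuals: {dup}")
        bad_sex = set(self.table["sex"].unique()) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"sex must be 'F' or 'M', got {sorted(bad_sex)}")
        wl = self.table["wing_length"]
        if (wl.dropna() <= 0).any():
            raise ValueError("wing_length must be positive where present")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, history: CaptureHistory) -> "CovariateTable":
        """Reorder rows to match the history's individual order."""
        idx = self.table.set_index("individual_id")
        missing = [i for i in history.individual_ids if i not in idx.index]
        if missing:
            raise ValueError(f"covariates missing for individuals: {missing}")
        out = idx.loc[history.individual_ids].reset_index()
        return CovariateTable(out)

    @classmethod
    def read(cls, path: str | Path, sep: str = ",") -> "CovariateTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=False)


@dataclass
class ResightSummary:
    """Resighting counts for one capture history, optionally against a second.

    ``n_resighted`` counts individuals detected at least once strictly after
    their first capture.  When a second history ``b`` is supplied,
    ``pct_increase = 100 * (n_b - n_a) / n_a``: the proportional increase in
    resighted individuals from history a to history b.
    """

    n_marked: int
    n_resighted: int
    pct_resighted: float
    n_resighted_b: int | None = None
    pct_resighted_b: float | None = None
    pct_increase: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: v for k, v in self.__dict__.items() if v is not None}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Reading and validating encounter files
# ---------------------------------------------------------------------------

@dataclass
class FileDialect:
    """How to interpret a long-format encounter file.

    ``survey_days``: ordered list of calendar-date strings; when the file has
    a ``date`` column instead of ``occasion``, each date is mapped to its
    1-based position in this list.  Occasions are treated as equally spaced
    regardless of calendar gaps (skipped bad-weather days are simply absent
    from the list).
    """

    sep: str = ","
    survey_days: Sequence[str] | None = None


def read_encounters(
    path: str | Path,
    T: int,
    dialect: FileDialect | None = None,
) -> list[EncounterRecord]:
    """Read and validate a long-format encounter file.

    The file needs columns ``individual_id``, ``occasion`` (or ``date``,
    resolved through ``dialect.survey_days``), ``channel`` and ``event``.
    Duplicate (individual, occasion, channel) rows are collapsed to one with
    a warning.  Raises ``ValueError`` on unknown channel labels, occasions
    outside 1..T, or a resight dated before the individual's initial capture.
    """
    dialect = dialect or FileDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype={"individual_id": str})

    if "occasion" not in df.columns:
        if "date" not in df.columns or dialect.survey_days is None:
            raise ValueError(
                "file must have an 'occasion' column, or a 'date' column "
                "with dialect.survey_days supplied"
            )
        day_index = {d: k + 1 for k, d in enumerate(dialect.survey_days)}
        unknown = sorted(set(df["date"].astype(str)) - set(day_index))
        if unknown:
            raise ValueError(f"dates not in survey_days: {unknown}")
        df["occasion"] = df["date"].astype(str).map(day_index)

    for col in ("individual_id", "occasion", "channel", "event"):
        if col not in df.columns:
            raise ValueError(f"encounter file missing column {col!r}")

    bad_channel = set(df["channel"].unique()) - {c.value for c in Channel}
    if bad_channel:
        raise ValueError(f"unknown channel labels: {sorted(bad_channel)}")
    bad_event = set(df["event"].unique()) - {ev.value for ev in Event}
    if bad_event:
        raise ValueError(f"unknown event labels: {sorted(bad_event)}")

    occ = df["occasion"].astype(int)
    out_of_range = df.loc[(occ < 1) | (occ > T)]
    if len(out_of_range):
        raise ValueError(
            f"occasions outside 1..{T}: "
            f"{sorted(out_of_range['occasion'].unique().tolist())}"
        )

    n_dup = df.duplicated(subset=["individual_id", "occasion", "channel"]).sum()
    if n_dup:
        logger.warning(
            "collapsed %d duplicate (individual, occasion, channel) rows", n_dup
        )
        df = df.drop_duplicates(subset=["individual_id", "occasion", "channel"])

    records = [
        EncounterRecord(
            individual_id=row.individual_id,
            occasion=int(row.occasion),
            channel=Channel(row.channel),
            event=Event(row.event),
        )
        for row in df.itertuples()
    ]

    first = {
        r.individual_id: r.occasion for r in records if r.event is Event.initial_capture
    }
    for r in records:
        if r.event is Event.resight and r.individual_id in first:
            if r.occasion < first[r.individual_id]:
                raise ValueError(
                    f"individual {r.individual_id!r} resighted at occasion "
                    f"{r.occasion}, before initial capture at {first[r.individual_id]}"
                )
    return records


def write_encounters(
    records: Iterable[EncounterRecord], path: str | Path, sep: str = ","
) -> None:
    """Write records to a long-format delimited file."""
    df = pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "occasion": r.occasion,
                "channel": r.channel.value,
                "event": r.event.value,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Building histories
# ---------------------------------------------------------------------------

def build_history(
    records: Iterable[EncounterRecord],
    channels: Iterable[Channel | str],
    T: int,
) -> CaptureHistory:
    """Collapse encounter records into a binary capture history.

    ``Y[i, t] = 1`` iff individual i has at least one record at occasion t+1
    in an included channel, or t+1 is its first-capture occasion.  Same-day
    detections by both channels contribute a single 1 (set-union semantics).
    ``channels={CV}`` yields the conventional-only dataset;
    ``channels={CV, HSV}`` the merged dataset.

    Every individual must have exactly one ``initial_capture`` record.
    """
    channels = {Channel(c) for c in channels}
    records = list(records)

    first: dict[str, int] = {}
    for r in records:
        if r.event is Event.initial_capture:
            if r.individual_id in first:
                raise ValueError(
                    f"individual {r.individual_id!r} has multiple initial captures"
                )
            first[r.individual_id] = r.occasion
    seen_ids = {r.individual_id for r in records}
    orphans = sorted(seen_ids - set(first))
    if orphans:
        raise ValueError(f"individuals with resights but no initial_capture: {orphans}")

    ids = sorted(first)
    index = {iid: i for i, iid in enumerate(ids)}
    Y = np.zeros((len(ids), T), dtype=np.int8)
    e = np.array([first[iid] for iid in ids], dtype=np.int64)
    Y[np.arange(len(ids)), e - 1] = 1
    for r in records:
        if r.channel in channels and r.occasion > first[r.individual_id]:
            Y[index[r.individual_id], r.occasion - 1] = 1
    return CaptureHistory(individual_ids=ids, T=T, Y=Y, e=e)


def validate_history(h: CaptureHistory) -> dict[str, list]:
    """Check CaptureHistory invariants, returning violations instead of raising.

    The report maps violation kind to the offending individual ids:

    - ``not_binary``: entries outside {0, 1}
    - ``first_capture_not_one``: Y[i, e_i] != 1
    - ``detection_before_first``: a 1 strictly before e_i
    - ``e_out_of_range``: e_i outside 1..T
    - ``captured_at_final_occasion``: informational; individuals first marked
      on the last day contribute a constant to the CJS likelihood.
    """
    report: dict[str, list] = {
        "not_binary": [],
        "first_capture_not_one": [],
        "detection_before_first": [],
        "e_out_of_range": [],
        "captured_at_final_occasion": [],
    }
    for i, iid in enumerate(h.individual_ids):
        row = h.Y[i]
        ei = int(h.e[i])
        if not np.isin(row, (0, 1)).all():
            report["not_binary"].append(iid)
            continue
        if ei < 1 or ei > h.T:
            report["e_out_of_range"].append(iid)
            continue
        if row[ei - 1] != 1:
            report["first_capture_not_one"].append(iid)
        if row[: ei - 1].any():
            report["detection_before_first"].append(iid)
        if ei == h.T:
            report["captured_at_final_occasion"].append(iid)
    return report


def is_valid(report: dict[str, list]) -> bool:
    """True when the report contains no hard violations (informational
    ``captured_at_final_occasion`` entries are allowed)."""
    return all(not v for k, v in report.items() if k != "captured_at_final_occasion")


# ---------------------------------------------------------------------------
# Resight summaries
# ---------------------------------------------------------------------------

def pct_increase(n_a: int, n_b: int) -> float:
    """Proportional increase 100*(n_b - n_a)/n_a, e.g. 28 -> 46 gives 64.29."""
    if n_a == 0:
        raise ZeroDivisionError("percent increase undefined when baseline count is 0")
    return 100.0 * (n_b - n_a) / n_a


def n_resighted(h: CaptureHistory) -> int:
    """Individuals detected at least once strictly after first capture."""
    cols = np.arange(1, h.T + 1)
    after = (h.Y == 1) & (cols[None, :] > h.e[:, None])
    return int(after.any(axis=1).sum())


def resight_summary(
    a: CaptureHistory, b: CaptureHistory | None = None
) -> ResightSummary:
    """Count resighted individuals, optionally contrasting two histories.

    With ``b`` given (same individuals and T, e.g. the CV and CV+HSV
    datasets), reports the proportional increase in resighted individuals.
    """
    na = n_resighted(a)
    out = ResightSummary(
        n_marked=a.n,
        n_resighted=na,
        pct_resighted=100.0 * na / a.n if a.n else 0.0,
    )
    if b is not None:
        if b.individual_ids != a.individual_ids or b.T != a.T:
            raise ValueError("histories must share individuals and T to compare")
        nb = n_resighted(b)
        out.n_resighted_b = nb
        out.pct_resighted_b = 100.0 * nb / b.n if b.n else 0.0
        out.pct_increase = pct_increase(na, nb)
    return out


# ---------------------------------------------------------------------------
# Wide-format interchange (one row per individual, T binary columns)
# ---------------------------------------------------------------------------

def write_wide_history(h: CaptureHistory, path: str | Path, sep: str = ",") -> None:
    """Write a capture history as id + T binary columns (mark-recapture
    interchange convention)."""
    cols = {f"occ{t}": h.Y[:, t - 1] for t in range(1, h.T + 1)}
    df = pd.DataFrame({"individual_id": h.individual_ids, **cols})
    df.to_csv(path, sep=sep, index=False)


def read_wide_history(path: str | Path, sep: str = ",") -> CaptureHistory:
    """Read a wide-format capture history; e is inferred as the first 1."""
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str})
    occ_cols = [c for c in df.columns if c.startswith("occ")]
    occ_cols.sort(key=lambda c: int(c[3:]))
    Y = df[occ_cols].to_numpy(dtype=np.int8)
    if not ((Y == 0) | (Y == 1)).all():
        raise ValueError("wide history entries must be 0 or 1")
    if (Y.sum(axis=1) == 0).any():
        raise ValueError("every individual needs at least one detection")
    e = Y.argmax(axis=1) + 1
    return CaptureHistory(
        individual_ids=df["individual_id"].tolist(), T=len(occ_cols), Y=Y, e=e
    )
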