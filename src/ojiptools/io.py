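"""Reading, validation and writing of fluorescence transients and trait tables.

Two delimited-text dialects are supported for transients:

``long_csv``
    Columns ``variety,treatment,replicate,time_us,fluorescence``; one row per
    sample, one (variety, treatment, replicate) group per trace.
``wide_csv``
    First column ``time_us``; every further column holds one trace and is
    named ``variety|treatment|replicate``.

Trait tables (:class:`GroupTable`) are tidy CSVs with columns
``variety,treatment,replicate,trait,value``.

Time is microseconds everywhere, on disk and in memory. Fluorescence stays
in instrument units; all downstream quantities are ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "FluorescenceTransient",
    "GroupTable",
    "read_transients",
    "write_transients",
    "read_group_table",
    "write_group_table",
]

LONG_COLUMNS = ("variety", "treatment", "replicate", "time_us", "fluorescence")
GROUP_COLUMNS = ("variety", "treatment", "replicate", "trait", "value")

#: A trace must start this early (µs) and reach at least this late to cover
#: the K/J/I landmarks with margin.
MAX_FIRST_TIME_US = 50.0
MIN_LAST_TIME_US = 300_000.0
MIN_TRACE_LENGTH = 30


@dataclass(frozen=True)
class FluorescenceTransient:
    """One replicate's OJIP trace with its grouping metadata.

    Parameters
    ----------
    times
        Sample times in microseconds, strictly increasing; the first sample
        must fall at or before 50 µs and the last at or after 300 000 µs.
    fluorescence
        Fluorescence in instrument units, finite and strictly positive,
        same length as ``times`` (at least 30 samples).
    variety, treatment
        Free-form group labels (e.g. ``"NH5"``, ``"24h"``).
    replicate
        Positive integer replicate id.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    variety: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fluorescence", fluo)
        label = f"{self.variety}/{self.treatment}/rep{self.replicate}"
        if times.ndim != 1 or fluo.ndim != 1:
            raise ValidationError(f"{label}: times and fluorescence must be 1-D")
        if len(times) != len(fluo):
            raise ValidationError(
                f"{label}: length mismatch ({len(times)} times, {len(fluo)} values)"
            )
        if len(times) < MIN_TRACE_LENGTH:
            raise ValidationError(
                f"{label}: trace has {len(times)} samples, need >= {MIN_TRACE_LENGTH}"
            )
        if not np.all(np.isfinite(times)):
            raise ValidationError(f"{label}: non-finite time values")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"{label}: times not strictly increasing at sample {i} "
                f"(t={times[i]:g} after t={times[i - 1]:g})"
            )
        if times[0] > MAX_FIRST_TIME_US:
            raise ValidationError(
                f"{label}: first sample at {times[0]:g} µs, must be <= {MAX_FIRST_TIME_US:g} µs"
            )
        if times[-1] < MIN_LAST_TIME_US:
            raise ValidationError(
                f"{label}: last sample at {times[-1]:g} µs, must be >= {MIN_LAST_TIME_US:g} µs"
            )
        if not np.all(np.isfinite(fluo)) or np.any(fluo <= 0):
            raise ValidationError(f"{label}: fluorescence must be finite and > 0")
        if not isinstance(self.replicate, (int, np.integer)) or self.replicate < 1:
            raise ValidationError(f"{label}: replicate must be a positive integer")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def group(self) -> tuple[str, str]:
        return (self.variety, self.treatment)


@dataclass
class GroupTable:
    """Tidy long table of trait values by variety x treatment x replicate.

    Wraps a :class:`pandas.DataFrame` with columns
    ``variety,treatment,replicate,trait,value`` and enforces that the key
    quadruple is unique and that every treatment label is present for every
    variety that appears.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(GROUP_COLUMNS)))

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in GROUP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"group table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(GROUP_COLUMNS)].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        df["variety"] = df["variety"].astype(str)
        df["treatment"] = df["treatment"].astype(str)
        df["trait"] = df["trait"].astype(str)
        key = ["variety", "treatment", "replicate", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(f"duplicate (variety,treatment,replicate,trait) key: {first}")
        if len(df):
            per_variety = df.groupby("variety")["treatment"].agg(frozenset)
            all_treatments = frozenset(df["treatment"])
            for variety, present in per_variety.items():
                lacking = all_treatments - present
                if lacking:
                    raise ValidationError(
                        f"variety {variety!r} missing treatment(s): {sorted(lacking)}"
                    )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroupTable):
            return NotImplemented
        key = ["variety", "treatment", "replicate", "trait"]
        a = self.df.sort_values(key).reset_index(drop=True)
        b = other.df.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, str, float]]
    ) -> "GroupTable":
        return cls(pd.DataFrame.from_records(list(records), columns=list(GROUP_COLUMNS)))

    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def varieties(self) -> list[str]:
        return sorted(self.df["variety"].unique())

    def subset(self, *, variety: str | None = None, trait: str | None = None) -> pd.DataFrame:
        """Filtered view as a plain DataFrame (no GroupTable invariants)."""
        df = self.df
        if variety is not None:
            df = df[df["variety"] == variety]
        if trait is not None:
            df = df[df["trait"] == trait]
        return df

    def concat(self, other: "GroupTable") -> "GroupTable":
        return GroupTable(pd.concat([self.df, other.df], ignore_index=True))


def read_transients(path: str | Path, dialect: str = "long_csv") -> list[FluorescenceTransient]:
    """Read transients from a delimited-text file.

    Raises :class:`FormatError` on missing columns and :class:`ValidationError`
    (naming the replicate and offending file row) on non-monotone times.
    """
    path = Path(path)
    if dialect == "long_csv":
        return _read_long(path)
    if dialect == "wide_csv":
        return _read_wide(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long(path: Path) -> list[FluorescenceTransient]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    out: list[FluorescenceTransient] = []
    n_rows = 0
    for (variety, treatment, replicate), grp in df.groupby(
        ["variety", "treatment", "replicate"], sort=False
    ):
        t = grp["time_us"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            # +2: header line plus 1-based indexing of the offending data row
            row = int(grp.index[bad[0] + 1]) + 2
            raise ValidationError(
                f"{path}: time not strictly increasing for "
                f"{variety}/{treatment}/rep{replicate} at file row {row}"
            )
        tr = FluorescenceTransient(
            times=t,
            fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            variety=str(variety),
            treatment=str(treatment),
            replicate=int(replicate),
        )
        out.append(tr)
        n_rows += len(tr)
    if n_rows != len(df):
        raise ValidationError(f"{path}: reader dropped rows ({n_rows} != {len(df)})")
    return out


def _read_wide(path: Path) -> list[FluorescenceTransient]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_us":
        raise FormatError(f"{path}: first column must be 'time_us', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no trace columns after 'time_us'")
    t = df["time_us"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: time not strictly increasing at file row {int(bad[0]) + 3}"
        )
    out = []
    for col in df.columns[1:]:
        parts = col.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"{path}: trace column {col!r} not of the form 'variety|treatment|replicate'"
            )
        variety, treatment, replicate = parts
        try:
            rep = int(replicate)
        except ValueError as exc:
            raise FormatError(f"{path}: replicate part of {col!r} is not an integer") from exc
        out.append(
            FluorescenceTransient(
                times=t.copy(),
                fluorescence=df[col].to_numpy(dtype=float),
                variety=variety,
                treatment=treatment,
                replicate=rep,
            )
        )
    return out


def write_transients(
    transients: Sequence[FluorescenceTransient], path: str | Path, dialect: str = "long_csv"
) -> None:
    """Write transients in the ``long_csv`` dialect (round-trips with the reader)."""
    if dialect != "long_csv":
        raise ValueError("only the long_csv dialect is written")
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "variety": tr.variety,
                "treatment": tr.treatment,
                "replicate": tr.replicate,
                "time_us": tr.times,
                "fluorescence": tr.fluorescence,
            }
        )
        for tr in transients
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(LONG_COLUMNS))
    )
    df.to_csv(path, index=False)


def read_group_table(path: str | Path) -> GroupTable:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    return GroupTable(df)


def write_group_table(table: GroupTable, path: str | Path) -> None:
    """Write a GroupTable CSV; values keep full precision so the round trip is exact."""
    table.df.to_csv(Path(path), index=False)
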