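"""GPS fix ingestion, quality filtering and trajectory segmentation.

Collars are programmed on a nominal 2-h schedule but fixes are missed when
the collar fails to connect, so a trajectory carries per-step gap flags;
downstream bridge construction refuses to span flagged gaps (a 2-h bridge
model is not calibrated for a 6-h step).

Coordinates must be planar (projected, metres). Inputs that look geographic
(every |x| <= 180 and |y| <= 90) are rejected rather than silently
reprojected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GpsFix",
    "Trajectory",
    "GpsReadReport",
    "read_gps_fixes",
    "filter_fixes",
    "segment_trajectory",
    "write_fixes_csv",
    "qc_report",
]

REQUIRED_COLUMNS = ("animal_id", "timestamp", "x", "y", "pdop")


class SchemaError(ValueError):
    """A required input column is missing."""


class InsufficientDataError(ValueError):
    """Not enough fixes to build the requested object."""


@dataclass(frozen=True)
class GpsFix:
    """One GPS relocation in projected planar coordinates (metres).

    ``pdop`` is the positional dilution of precision of the fix
    (dimensionless, >= 0; larger is worse).
    """

    animal_id: str
    timestamp: datetime
    x: float
    y: float
    pdop: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.animal_id}")
        if not (math.isfinite(self.pdop) and self.pdop >= 0):
            raise ValueError(f"pdop must be finite and >= 0, got {self.pdop}")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal plus per-step gap flags.

    ``gap_flags[i]`` is True when the step from ``fixes[i]`` to
    ``fixes[i+1]`` exceeds ``nominal_interval * gap_tolerance``.
    """

    animal_id: str
    fixes: list[GpsFix]
    nominal_interval: timedelta = timedelta(hours=2)
    gap_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> list[datetime]:
        return [f.timestamp for f in self.fixes]

    def xy(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float)

    def step_hours(self) -> np.ndarray:
        t = self.times
        return np.array(
            [(t[i + 1] - t[i]).total_seconds() / 3600.0 for i in range(len(t) - 1)]
        )


@dataclass
class GpsReadReport:
    """Parsed fixes plus an audit of rows that could not be used."""

    fixes: list[GpsFix]
    skipped: list[tuple[int, str]]

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _looks_geographic(xs: np.ndarray, ys: np.ndarray) -> bool:
    if len(xs) == 0:
        return False
    return bool(np.all(np.abs(xs) <= 180.0) and np.all(np.abs(ys) <= 90.0))


def read_gps_fixes(path, crs: str = "projected") -> GpsReadReport:
    """Read a fix table (CSV: animal_id,timestamp,x,y,pdop; ISO-8601 times).

    Rows with unparseable fields are skipped and reported, never silently
    dropped. Raises :class:`SchemaError` when a required column is absent
    and ``ValueError`` on an empty file or geographic-looking coordinates.
    """
    df = pd.read_csv(path, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if len(df) == 0:
        raise ValueError(f"empty GPS input: {path}")

    fixes: list[GpsFix] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
            fix = GpsFix(
                animal_id=str(row.animal_id),
                timestamp=ts,
                x=float(row.x),
                y=float(row.y),
                pdop=float(row.pdop),
            )
        except (TypeError, ValueError) as exc:
            skipped.append((i, str(exc)))
            continue
        fixes.append(fix)

    if crs != "geographic-ok":
        xs = np.array([f.x for f in fixes])
        ys = np.array([f.y for f in fixes])
        if _looks_geographic(xs, ys):
            raise ValueError(
                "coordinates look geographic (lon/lat); supply projected "
                "planar coordinates in metres"
            )
    seen: set[tuple[str, datetime]] = set()
    deduped: list[GpsFix] = []
    for j, f in enumerate(fixes):
        key = (f.animal_id, f.timestamp)
        if key in seen:
            skipped.append((j, f"duplicate (animal_id, timestamp): {key}"))
        else:
            seen.add(key)
            deduped.append(f)
    return GpsReadReport(fixes=deduped, skipped=skipped)


def filter_fixes(fixes: Iterable[GpsFix], pdop_max: float = 10.0) -> list[GpsFix]:
    """Keep fixes with pdop strictly below ``pdop_max`` (default 10), order
    preserved. Idempotent; an empty result is allowed."""
    if pdop_max <= 0:
        raise ValueError("pdop_max must be > 0")
    return [f for f in fixes if f.pdop < pdop_max]


def segment_trajectory(
    fixes: Sequence[GpsFix],
    nominal_interval: timedelta = timedelta(hours=2),
    gap_tolerance: float = 1.5,
) -> Trajectory:
    """Sort one animal's fixes by time and flag steps longer than
    ``nominal_interval * gap_tolerance``.

    No fix is dropped: the output fix count equals the input count, and the
    result is invariant to the input ordering.
    """
    fixes = list(fixes)
    if len(fixes) < 2:
        raise InsufficientDataError("need at least 2 fixes to segment a trajectory")
    ids = {f.animal_id for f in fixes}
    if len(ids) > 1:
        raise ValueError(f"mixed animal ids in input: {sorted(ids)}")
    fixes.sort(key=lambda f: f.timestamp)
    for a, b in zip(fixes, fixes[1:]):
        if a.timestamp == b.timestamp:
            raise ValueError(f"duplicate timestamp {a.timestamp} for {a.animal_id}")
    limit = nominal_interval.total_seconds() * gap_tolerance
    flags = np.array(
        [
            (b.timestamp - a.timestamp).total_seconds() > limit
            for a, b in zip(fixes, fixes[1:])
        ],
        dtype=bool,
    )
    return Trajectory(
        animal_id=fixes[0].animal_id,
        fixes=fixes,
        nominal_interval=nominal_interval,
        gap_flags=flags,
    )


def write_fixes_csv(fixes: Iterable[GpsFix], path) -> None:
    df = pd.DataFrame(
        [
            {
                "animal_id": f.animal_id,
                "timestamp": f.timestamp.isoformat(),
                "x": f.x,
                "y": f.y,
                "pdop": f.pdop,
            }
            for f in fixes
        ]
    )
    df.to_csv(path, index=False)


def qc_report(
    raw: GpsReadReport, kept: Sequence[GpsFix], trajectories: dict[str, Trajectory]
) -> dict:
    """Counts for the audit trail: parse skips, PDOP removals, flagged gaps."""
    return {
        "rows_parsed": len(raw.fixes) + raw.n_skipped,
        "rows_skipped": raw.n_skipped,
        "fixes_before_pdop_filter": len(raw.fixes),
        "fixes_after_pdop_filter": len(kept),
        "removed_by_pdop": len(raw.fixes) - len(kept),
        "gaps_flagged": {a: int(t.gap_flags.sum()) for a, t in trajectories.items()},
    }
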