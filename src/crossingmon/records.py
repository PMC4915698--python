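"""Trigger-record and structure data model with CSV I/O.

A *trigger record* is one camera activation: the camera fires, stores a
photograph plus a short movie, and the pair is logged as a single row with
the structure, camera, timestamp, species and the number of individuals
visible.  Records are the raw input of the analysis; deduplicated *events*
are derived from them downstream.

CSV schemas (comma-separated, UTF-8, mandatory header, ISO 8601 timestamps):

* triggers:   ``structure_id,camera_id,timestamp,species,count,media``
* structures: ``structure_id,structure_class,n_cameras,pack_id,first_year,last_year``
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calendars import MonitoringCalendar

__all__ = [
    "SPECIES",
    "PREY_SPECIES",
    "STRUCTURE_CLASSES",
    "TriggerRecord",
    "StructureInfo",
    "RecordValidationError",
    "read_trigger_records",
    "write_trigger_records",
    "records_to_frame",
    "frame_to_records",
    "read_structures",
    "write_structures",
    "import_supplementary",
]

#: Closed species vocabulary. "other" keeps non-focal detections countable so
#: whole-study event totals (the percentage denominators) remain computable.
SPECIES = ("wolf", "wild_boar", "red_deer", "roe_deer", "other")

#: The wolf's natural prey species tracked by the analysis.
PREY_SPECIES = ("roe_deer", "red_deer", "wild_boar")

STRUCTURE_CLASSES = ("green_bridge", "viaduct")

TRIGGER_COLUMNS = ["structure_id", "camera_id", "timestamp", "species", "count", "media"]
STRUCTURE_COLUMNS = [
    "structure_id",
    "structure_class",
    "n_cameras",
    "pack_id",
    "first_year",
    "last_year",
]


class RecordValidationError(ValueError):
    """Invalid rows in an input file; message lists offending line numbers."""


@dataclass(frozen=True)
class TriggerRecord:
    """One camera activation (photograph + movie logged as a single unit).

    Timestamps are naive local time; camera clocks are assumed synchronized
    within a structure.
    """

    structure_id: str
    camera_id: str
    timestamp: datetime
    species: str
    count: int
    media: str = "photo_movie"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise RecordValidationError(
                f"unknown species token {self.species!r}; expected one of {SPECIES}"
            )
        if self.count < 1:
            raise RecordValidationError(f"count must be >= 1, got {self.count}")
        if not isinstance(self.timestamp, datetime):
            raise RecordValidationError(f"unparseable timestamp: {self.timestamp!r}")


@dataclass(frozen=True)
class StructureInfo:
    """A monitored crossing structure and its camera/pack configuration."""

    structure_id: str
    structure_class: str
    n_cameras: int
    pack_id: str
    monitored_years: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(
                f"structure_class must be one of {STRUCTURE_CLASSES}, "
                f"got {self.structure_class!r}"
            )
        if self.n_cameras < 1:
            raise ValueError("n_cameras must be >= 1")


def _parse_row(row: dict, lineno: int) -> TriggerRecord:
    try:
        ts = datetime.fromisoformat(row["timestamp"])
    except (ValueError, TypeError) as exc:
        raise RecordValidationError(
            f"line {lineno}: unparseable timestamp {row.get('timestamp')!r}"
        ) from exc
    try:
        count = int(row["count"])
    except (ValueError, TypeError) as exc:
        raise RecordValidationError(
            f"line {lineno}: count is not an integer ({row.get('count')!r})"
        ) from exc
    try:
        return TriggerRecord(
            structure_id=row["structure_id"],
            camera_id=row["camera_id"],
            timestamp=ts,
            species=row["species"],
            count=count,
            media=row.get("media") or "photo_movie",
        )
    except RecordValidationError as exc:
        raise RecordValidationError(f"line {lineno}: {exc}") from exc


def read_trigger_records(path: str | Path) -> list[TriggerRecord]:
    """Read and validate a trigger CSV.

    Every row is validated; a :class:`RecordValidationError` naming the
    offending line numbers is raised if any row is invalid.  The returned
    list is ordered by ``(structure_id, timestamp, camera_id)``.
    """
    path = Path(path)
    records: list[TriggerRecord] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in TRIGGER_COLUMNS if c not in reader.fieldnames
        ]:
            raise RecordValidationError(
                f"{path}: header must contain columns {TRIGGER_COLUMNS}, "
                f"found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, lineno))
            except RecordValidationError as exc:
                errors.append(str(exc))
    if errors:
        raise RecordValidationError(f"{path}: " + "; ".join(errors))
    records.sort(key=lambda r: (r.structure_id, r.timestamp, r.camera_id))
    return records


def write_trigger_records(
    records: Iterable[TriggerRecord], path: str | Path
) -> Path:
    """Write records to the trigger CSV schema (header always written)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIGGER_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.structure_id,
                    r.camera_id,
                    r.timestamp.isoformat(),
                    r.species,
                    r.count,
                    r.media,
                ]
            )
    return path


def records_to_frame(records: Sequence[TriggerRecord]) -> pd.DataFrame:
    """Trigger records as a DataFrame with the trigger CSV columns."""
    return pd.DataFrame(
        [
            (r.structure_id, r.camera_id, r.timestamp, r.species, r.count, r.media)
            for r in records
        ],
        columns=TRIGGER_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[TriggerRecord]:
    records = []
    for row in frame.itertuples(index=False):
        ts = row.timestamp
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        elif isinstance(ts, pd.Timestamp):
            ts = ts.to_pydatetime()
        records.append(
            TriggerRecord(
                structure_id=str(row.structure_id),
                camera_id=str(row.camera_id),
                timestamp=ts,
                species=str(row.species),
                count=int(row.count),
                media=str(getattr(row, "media", "photo_movie")),
            )
        )
    records.sort(key=lambda r: (r.structure_id, r.timestamp, r.camera_id))
    return records


def read_structures(
    path: str | Path, calendar: MonitoringCalendar
) -> list[StructureInfo]:
    """Read the structures CSV; monitored years are expanded from the
    ``first_year``/``last_year`` labels against ``calendar``."""
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in STRUCTURE_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing columns {missing}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            StructureInfo(
                structure_id=row.structure_id,
                structure_class=row.structure_class,
                n_cameras=int(row.n_cameras),
                pack_id=row.pack_id,
                monitored_years=tuple(
                    calendar.span_labels(row.first_year, row.last_year)
                ),
            )
        )
    return out


def write_structures(structures: Sequence[StructureInfo], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STRUCTURE_COLUMNS)
        for s in structures:
            writer.writerow(
                [
                    s.structure_id,
                    s.structure_class,
                    s.n_cameras,
                    s.pack_id,
                    s.monitored_years[0],
                    s.monitored_years[-1],
                ]
            )
    return path


_SUMMARY_HINT_COLUMNS = {"pack_id", "monitoring_year", "n_events_wolf"}


def import_supplementary(path: str | Path):
    """Import a supplementary spreadsheet into the pipeline's schemas.

    The workbook may hold either raw trigger-level rows or annual per-pack
    aggregates; which one was found is detected from the header and returned
    alongside the data.

    Returns
    -------
    (kind, data)
        ``("triggers", list[TriggerRecord])`` when the sheet carries the
        trigger schema, or ``("summaries", DataFrame)`` when it carries
        annual aggregates (at least pack, monitoring year and wolf event
        counts).
    """
    frame = pd.read_excel(path, engine="openpyxl")
    cols = set(map(str, frame.columns))
    if set(TRIGGER_COLUMNS) <= cols:
        return "triggers", frame_to_records(frame[TRIGGER_COLUMNS])
    if _SUMMARY_HINT_COLUMNS <= cols:
        return "summaries", frame
    raise RecordValidationError(
        f"{path}: sheet is neither trigger-level (needs {TRIGGER_COLUMNS}) nor "
        f"aggregate (needs at least {sorted(_SUMMARY_HINT_COLUMNS)}); "
        f"found columns {sorted(cols)}"
    )
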