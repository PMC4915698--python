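"""Per-pack annual abundance summaries, effort arithmetic and trend tables.

Each monitored pack is observed through the crossing structures inside its
home range; events recorded on any of a pack's structures are attributed to
that pack.  The two abundance indices per pack and monitoring year are the
number of wolf events (a relative abundance index, valid insofar as crossing
frequency scales with abundance) and the minimal pack size (the largest
group seen in one event — a lower bound on true pack size).

Summary CSV schema: ``pack_id,monitoring_year,n_events_total,n_events_wolf,
n_events_prey,minimal_pack_size,trap_days`` plus per-species prey columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .events import Event
from .records import PREY_SPECIES, StructureInfo

__all__ = [
    "AnnualPackSummary",
    "ConfigurationError",
    "annual_pack_summary",
    "trap_days",
    "camera_density",
    "trend_table",
    "plot_trends",
    "summaries_to_frame",
    "frame_to_summaries",
    "read_summaries",
    "write_summaries",
]

#: Days per monitoring year used in effort arithmetic (leap days ignored:
#: a five-year green bridge with 4 cameras gives the conventional 7300
#: trap-days).
DAYS_PER_MONITORING_YEAR = 365

SUMMARY_COLUMNS = [
    "pack_id",
    "monitoring_year",
    "n_events_total",
    "n_events_wolf",
    "n_events_prey",
    "n_events_roe_deer",
    "n_events_red_deer",
    "n_events_wild_boar",
    "minimal_pack_size",
    "trap_days",
]


class ConfigurationError(ValueError):
    """Raised when events reference structures absent from the configuration."""


@dataclass(frozen=True)
class AnnualPackSummary:
    """Counts and indices for one pack in one monitoring year."""

    pack_id: str
    monitoring_year: str
    n_events_total: int
    n_events_wolf: int
    n_events_prey: int
    n_events_roe_deer: int
    n_events_red_deer: int
    n_events_wild_boar: int
    minimal_pack_size: int
    trap_days: int

    def __post_init__(self) -> None:
        if min(
            self.n_events_total,
            self.n_events_wolf,
            self.n_events_prey,
            self.minimal_pack_size,
            self.trap_days,
        ) < 0:
            raise ValueError("summary counts must be non-negative")
        if (self.minimal_pack_size == 0) != (self.n_events_wolf == 0):
            raise ValueError(
                "minimal_pack_size must be zero exactly when there are no wolf "
                f"events (pack {self.pack_id}, year {self.monitoring_year})"
            )


def trap_days(n_cameras: int, n_days: int) -> int:
    """Sampling effort: camera-days of continuous operation."""
    if n_cameras < 0 or n_days < 0:
        raise ValueError("n_cameras and n_days must be non-negative")
    return n_cameras * n_days


def camera_density(n_cameras: int, area_km2: float, decimals: int = 2) -> float:
    """Camera traps per square kilometre, half-up rounded."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be positive")
    return round_half_up(n_cameras / area_km2, decimals)


def annual_pack_summary(
    events: Iterable[Event],
    structures: Sequence[StructureInfo],
    years: Sequence[str],
) -> list[AnnualPackSummary]:
    """Aggregate events into one row per pack and monitoring year.

    Events are summed over all structures assigned to a pack; zero rows are
    emitted for monitored years with no events, and the minimal pack size is
    the largest wolf-event count in the pack-year.  Effort (``trap_days``)
    sums ``n_cameras * 365`` over the pack's structures monitored that year.

    Raises
    ------
    ConfigurationError
        If any event references a structure not in ``structures``.
    """
    by_structure = {s.structure_id: s for s in structures}
    packs: dict[str, list[StructureInfo]] = {}
    for s in structures:
        packs.setdefault(s.pack_id, []).append(s)

    # pack -> year -> accumulators
    acc: dict[tuple[str, str], dict] = {}
    for pack_id, members in packs.items():
        for year in years:
            if any(year in s.monitored_years for s in members):
                acc[(pack_id, year)] = {
                    "total": 0,
                    "wolf": 0,
                    "prey": {sp: 0 for sp in PREY_SPECIES},
                    "minpack": 0,
                }

    for e in events:
        s = by_structure.get(e.structure_id)
        if s is None:
            raise ConfigurationError(
                f"event at unmapped structure {e.structure_id!r}; "
                "every structure must be assigned to a pack"
            )
        key = (s.pack_id, e.monitoring_year)
        if key not in acc:
            if e.monitoring_year not in years:
                continue
            # event in a year the structure was not declared monitored:
            # count it rather than silently drop it
            acc[key] = {
                "total": 0,
                "wolf": 0,
                "prey": {sp: 0 for sp in PREY_SPECIES},
                "minpack": 0,
            }
        a = acc[key]
        a["total"] += 1
        if e.species == "wolf":
            a["wolf"] += 1
            a["minpack"] = max(a["minpack"], e.count)
        elif e.species in a["prey"]:
            a["prey"][e.species] += 1

    out: list[AnnualPackSummary] = []
    for pack_id in sorted(packs):
        members = packs[pack_id]
        for year in years:
            key = (pack_id, year)
            if key not in acc:
                continue
            a = acc[key]
            effort = sum(
                trap_days(s.n_cameras, DAYS_PER_MONITORING_YEAR)
                for s in members
                if year in s.monitored_years
            )
            out.append(
                AnnualPackSummary(
                    pack_id=pack_id,
                    monitoring_year=year,
                    n_events_total=a["total"],
                    n_events_wolf=a["wolf"],
                    n_events_prey=sum(a["prey"].values()),
                    n_events_roe_deer=a["prey"]["roe_deer"],
                    n_events_red_deer=a["prey"]["red_deer"],
                    n_events_wild_boar=a["prey"]["wild_boar"],
                    minimal_pack_size=a["minpack"],
                    trap_days=effort,
                )
            )
    return out


def trend_table(summaries: Sequence[AnnualPackSummary]) -> pd.DataFrame:
    """Ordered per-pack trend series (events and minimal pack size by year).

    Years within each pack are sorted in calendar order; a pack-year present
    in the input with no events appears as an explicit zero row.
    """
    if not summaries:
        raise ValueError("summaries must be non-empty")
    frame = summaries_to_frame(summaries)
    frame = frame.sort_values(["pack_id", "monitoring_year"]).reset_index(drop=True)
    return frame[
        [
            "pack_id",
            "monitoring_year",
            "n_events_wolf",
            "minimal_pack_size",
            "n_events_prey",
            "n_events_total",
        ]
    ]


def plot_trends(
    summaries: Sequence[AnnualPackSummary],
    path: str | Path | None = None,
):
    """Bar chart of wolf events per pack-year with minimal pack size labels.

    Returns the matplotlib figure; saves to ``path`` when given.  Uses the
    non-interactive backend so it is safe in headless runs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = trend_table(summaries)
    packs = table["pack_id"].unique()
    fig, axes = plt.subplots(
        len(packs), 1, figsize=(7, 2.4 * len(packs)), squeeze=False, sharex=False
    )
    for ax, pack in zip(axes.ravel(), packs):
        sub = table[table["pack_id"] == pack]
        ax.bar(sub["monitoring_year"], sub["n_events_wolf"], color="#4477aa")
        for x, (n, m) in enumerate(
            zip(sub["n_events_wolf"], sub["minimal_pack_size"])
        ):
            ax.annotate(str(m), (x, n), ha="center", va="bottom", fontsize=8)
        ax.set_ylabel("wolf events")
        ax.set_title(pack, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def summaries_to_frame(summaries: Sequence[AnnualPackSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            tuple(getattr(s, c) for c in SUMMARY_COLUMNS)
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )


def frame_to_summaries(frame: pd.DataFrame) -> list[AnnualPackSummary]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            AnnualPackSummary(
                pack_id=str(row.pack_id),
                monitoring_year=str(row.monitoring_year),
                n_events_total=int(row.n_events_total),
                n_events_wolf=int(row.n_events_wolf),
                n_events_prey=int(row.n_events_prey),
                n_events_roe_deer=int(getattr(row, "n_events_roe_deer", 0)),
                n_events_red_deer=int(getattr(row, "n_events_red_deer", 0)),
                n_events_wild_boar=int(getattr(row, "n_events_wild_boar", 0)),
                minimal_pack_size=int(row.minimal_pack_size),
                trap_days=int(row.trap_days),
            )
        )
    return out


def write_summaries(summaries: Sequence[AnnualPackSummary], path: str | Path) -> Path:
    path = Path(path)
    summaries_to_frame(summaries).to_csv(path, index=False)
    return path


def read_summaries(path: str | Path) -> list[AnnualPackSummary]:
    return frame_to_summaries(pd.read_csv(path))
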