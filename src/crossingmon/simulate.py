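"""Seeded simulator of camera-trap trigger records on crossing structures.

The simulator emulates the detection process the analysis assumes so the
whole pipeline is testable without field data.  Per structure and day,
crossing episodes arrive as a Poisson process: the wolf rate scales with the
pack size of the pack using the structure (``crossing_rate_per_wolf x pack
size``), and each prey species has its own background rate.  A crossing
brings a group (zero-truncated Poisson group size, capped at the pack size
for wolves), dwells on the structure for an exponential time, and repeatedly
triggers the cameras at the minimum inter-record delay while it stays.
Several cameras on one structure may film the same passage, and a crossing
can be missed outright — which is exactly the redundancy and loss the
downstream deduplication rule and relative-abundance reading must cope with.

Every draw flows from one seed, so a fixed configuration reproduces its
record stream byte for byte.  The companion truth table (true pack size,
number of crossing episodes and largest group per pack-year) lets tests
bound what the pipeline recovers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calendars import MonitoringCalendar
from .records import (
    STRUCTURE_CLASSES,
    StructureInfo,
    TriggerRecord,
    write_trigger_records,
)

__all__ = [
    "ConfigError",
    "StructureSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_trigger_records",
    "write_fixture",
    "study_default_config",
    "simulate_cull_effect_series",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class StructureSpec:
    structure_id: str
    structure_class: str
    n_cameras: int

    def __post_init__(self) -> None:
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ConfigError(
                f"structure_class must be one of {STRUCTURE_CLASSES}, "
                f"got {self.structure_class!r}"
            )
        if self.n_cameras < 1:
            raise ConfigError("n_cameras must be >= 1")


def _year_sort_key(label: str) -> int:
    return int(label.split("/")[0])


@dataclass
class SimulationConfig:
    """Study design and detection-process parameters.

    Parameters
    ----------
    structures
        Monitored crossing structures with their camera counts.
    pack_map
        ``structure_id -> pack_id``; every structure must be mapped.
    pack_trajectories
        ``pack_id -> {monitoring-year label -> pack size}``.  All packs must
        cover the same year labels.
    crossing_rate_per_wolf
        Expected crossings per structure, day and pack member.
    mean_group_fraction
        Expected fraction of the pack crossing together, in (0, 1].
    dwell_mean_s
        Mean dwell time on the structure (seconds, exponential).
    trigger_delay_s
        Camera refractory period: minimum seconds between two records from
        one camera.
    miss_prob
        Probability a crossing leaves no record at all, in [0, 1).
    camera_detect_prob
        Probability each camera independently films a non-missed crossing
        (at least one always does).
    prey_rates
        ``species -> expected crossings per structure and day`` for the
        background streams (prey species and "other").
    prey_group_mean
        Mean of the zero-truncated Poisson group size for non-wolf species.
    undercount_prob
        Probability a record under-reports the group by one (floor 1).
    structure_years
        Optional ``structure_id -> list of year labels`` restricting when a
        structure was monitored (default: the full trajectory span).
    outages
        Optional ``structure_id -> [(start, end), ...]`` ISO datetimes;
        no records are emitted inside an outage window (crossings still
        count as truth).
    """

    structures: Sequence[StructureSpec]
    pack_map: Mapping[str, str]
    pack_trajectories: Mapping[str, Mapping[str, int]]
    crossing_rate_per_wolf: float = 0.01
    mean_group_fraction: float = 0.4
    dwell_mean_s: float = 90.0
    trigger_delay_s: float = 60.0
    miss_prob: float = 0.1
    camera_detect_prob: float = 0.8
    prey_rates: Mapping[str, float] = field(default_factory=dict)
    prey_group_mean: float = 1.8
    undercount_prob: float = 0.0
    structure_years: Mapping[str, Sequence[str]] | None = None
    outages: Mapping[str, Sequence[tuple[str, str]]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.structures = [
            s if isinstance(s, StructureSpec) else StructureSpec(*s)
            for s in self.structures
        ]
        self.validate()

    def validate(self) -> None:
        ids = {s.structure_id for s in self.structures}
        unknown = set(self.pack_map) - ids
        if unknown:
            raise ConfigError(f"pack_map references unknown structures {sorted(unknown)}")
        unmapped = ids - set(self.pack_map)
        if unmapped:
            raise ConfigError(f"structures not assigned to a pack: {sorted(unmapped)}")
        if not self.pack_trajectories:
            raise ConfigError("pack_trajectories must not be empty")
        label_sets = {
            pack: tuple(sorted(traj, key=_year_sort_key))
            for pack, traj in self.pack_trajectories.items()
        }
        labels = set(label_sets.values())
        if len(labels) != 1:
            raise ConfigError(
                "all packs must cover identical monitoring-year labels; "
                f"got {sorted(labels)}"
            )
        if not next(iter(labels)):
            raise ConfigError("pack trajectories cover no monitoring years")
        for pack in set(self.pack_map.values()):
            if pack not in self.pack_trajectories:
                raise ConfigError(f"no trajectory for pack {pack!r}")
        for traj in self.pack_trajectories.values():
            if any(v < 0 for v in traj.values()):
                raise ConfigError("pack sizes must be non-negative")
        if self.crossing_rate_per_wolf < 0:
            raise ConfigError("crossing_rate_per_wolf must be >= 0")
        if any(r < 0 for r in self.prey_rates.values()):
            raise ConfigError("prey rates must be >= 0")
        if not 0 <= self.miss_prob < 1:
            raise ConfigError("miss_prob must lie in [0, 1)")
        if not 0 < self.mean_group_fraction <= 1:
            raise ConfigError("mean_group_fraction must lie in (0, 1]")
        if self.dwell_mean_s <= 0 or self.trigger_delay_s <= 0:
            raise ConfigError("dwell_mean_s and trigger_delay_s must be positive")
        if not 0 < self.camera_detect_prob <= 1:
            raise ConfigError("camera_detect_prob must lie in (0, 1]")

    @property
    def year_labels(self) -> list[str]:
        any_traj = next(iter(self.pack_trajectories.values()))
        return sorted(any_traj, key=_year_sort_key)

    def calendar(self) -> MonitoringCalendar:
        labels = self.year_labels
        return MonitoringCalendar(_year_sort_key(labels[0]), len(labels))

    def years_of(self, structure_id: str) -> list[str]:
        if self.structure_years and structure_id in self.structure_years:
            return sorted(self.structure_years[structure_id], key=_year_sort_key)
        return self.year_labels

    def structure_infos(self) -> list[StructureInfo]:
        """The configuration expressed as downstream structure metadata."""
        return [
            StructureInfo(
                structure_id=s.structure_id,
                structure_class=s.structure_class,
                n_cameras=s.n_cameras,
                pack_id=self.pack_map[s.structure_id],
                monitored_years=tuple(self.years_of(s.structure_id)),
            )
            for s in self.structures
        ]


@dataclass
class TruthTable:
    """Ground truth per pack and monitoring year."""

    frame: pd.DataFrame  # pack_id, monitoring_year, pack_size, n_crossings, max_group_size

    COLUMNS = ["pack_id", "monitoring_year", "pack_size", "n_crossings", "max_group_size"]

    def lookup(self, pack_id: str, year: str) -> pd.Series:
        sub = self.frame[
            (self.frame["pack_id"] == pack_id)
            & (self.frame["monitoring_year"] == year)
        ]
        if sub.empty:
            raise KeyError((pack_id, year))
        return sub.iloc[0]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(path))


def _zt_poisson(rng: np.random.Generator, mean: float, cap: int | None = None) -> int:
    """Zero-truncated Poisson draw (simple rejection), optionally capped."""
    if mean <= 0:
        k = 1
    else:
        k = 0
        while k == 0:
            k = int(rng.poisson(mean))
    if cap is not None:
        k = min(k, cap)
    return max(k, 1)


def _in_outage(ts: datetime, windows: list[tuple[datetime, datetime]]) -> bool:
    return any(a <= ts <= b for a, b in windows)


def simulate_trigger_records(
    config: SimulationConfig,
) -> tuple[list[TriggerRecord], TruthTable]:
    """Generate a trigger-record stream and its ground-truth table.

    Identical configurations (including the seed) give identical output.
    The returned records are ordered by ``(structure_id, timestamp,
    camera_id)``.
    """
    rng = np.random.default_rng(config.seed)
    calendar = config.calendar()
    delay = timedelta(seconds=config.trigger_delay_s)

    outages: dict[str, list[tuple[datetime, datetime]]] = {}
    for sid, windows in (config.outages or {}).items():
        outages[sid] = [
            (datetime.fromisoformat(str(a)), datetime.fromisoformat(str(b)))
            for a, b in windows
        ]

    truth_acc: dict[tuple[str, str], dict] = {}
    for pack_id, traj in config.pack_trajectories.items():
        for year in config.year_labels:
            truth_acc[(pack_id, year)] = {
                "pack_size": int(traj[year]),
                "n_crossings": 0,
                "max_group_size": 0,
            }

    records: list[TriggerRecord] = []

    for spec in sorted(config.structures, key=lambda s: s.structure_id):
        sid = spec.structure_id
        pack_id = config.pack_map[sid]
        windows = outages.get(sid, [])

        # collect crossing episodes for this structure, chronologically
        episodes: list[tuple[datetime, str, int, float, bool]] = []
        for year_label in config.years_of(sid):
            year = calendar.year(year_label)
            days = pd.date_range(year.start, year.end, freq="D")
            n_days = len(days)
            pack_size = int(config.pack_trajectories[pack_id][year_label])

            streams: list[tuple[str, float]] = []
            wolf_mu = config.crossing_rate_per_wolf * pack_size
            streams.append(("wolf", wolf_mu))
            for sp in sorted(config.prey_rates):
                streams.append((sp, float(config.prey_rates[sp])))

            for species, mu in streams:
                if mu <= 0:
                    continue
                daily = rng.poisson(mu, size=n_days)
                for day_idx in np.flatnonzero(daily):
                    day_start = days[day_idx].to_pydatetime()
                    for _ in range(int(daily[day_idx])):
                        t0 = day_start + timedelta(
                            seconds=int(rng.integers(0, 86400))
                        )
                        if species == "wolf":
                            group = _zt_poisson(
                                rng,
                                config.mean_group_fraction * pack_size,
                                cap=pack_size,
                            )
                        else:
                            group = _zt_poisson(rng, config.prey_group_mean)
                        dwell = float(rng.exponential(config.dwell_mean_s))
                        missed = bool(rng.random() < config.miss_prob)
                        episodes.append((t0, species, group, dwell, missed))
                        if species == "wolf":
                            t = truth_acc[(pack_id, year_label)]
                            t["n_crossings"] += 1
                            t["max_group_size"] = max(t["max_group_size"], group)

        episodes.sort(key=lambda e: e[0])

        last_record: dict[int, datetime] = {}
        for t0, species, group, dwell, missed in episodes:
            if missed or _in_outage(t0, windows):
                continue
            observing = [
                cam
                for cam in range(spec.n_cameras)
                if rng.random() < config.camera_detect_prob
            ]
            if not observing:
                observing = [int(rng.integers(0, spec.n_cameras))]
            n_triggers = 1 + int(dwell // config.trigger_delay_s)
            count = group
            if config.undercount_prob and rng.random() < config.undercount_prob:
                count = max(1, group - 1)
            for cam in observing:
                for k in range(n_triggers):
                    cand = t0 + timedelta(seconds=k * config.trigger_delay_s)
                    prev = last_record.get(cam)
                    if prev is not None and cand < prev + delay:
                        cand = prev + delay
                        # dwell repeats that cannot fire while the animal is
                        # still present are lost; the first record of the
                        # crossing is always kept (shifted) so a non-missed
                        # crossing emits at least one record
                        if k > 0 and (cand - t0).total_seconds() > dwell:
                            continue
                    last_record[cam] = cand
                    records.append(
                        TriggerRecord(
                            structure_id=sid,
                            camera_id=f"{sid}-cam{cam + 1}",
                            timestamp=cand,
                            species=species,
                            count=count,
                        )
                    )

    records.sort(key=lambda r: (r.structure_id, r.timestamp, r.camera_id))

    truth_rows = [
        {
            "pack_id": pack_id,
            "monitoring_year": year,
            **vals,
        }
        for (pack_id, year), vals in sorted(truth_acc.items())
    ]
    truth = TruthTable(pd.DataFrame(truth_rows, columns=TruthTable.COLUMNS))
    return records, truth


def write_fixture(
    records: Sequence[TriggerRecord],
    truth: TruthTable,
    directory: str | Path,
    config: SimulationConfig | None = None,
    allow_empty: bool = False,
) -> dict[str, Path]:
    """Write a simulated fixture (triggers, truth, config echo) to a directory.

    Files round-trip losslessly through the package readers.  An empty
    record stream is rejected unless ``allow_empty`` is set (a header-only
    CSV is then written).
    """
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty fixture; pass allow_empty=True")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "triggers": write_trigger_records(records, directory / "triggers.csv"),
        "truth": truth.write_csv(directory / "truth.csv"),
    }
    if config is not None:
        echo = asdict(config)
        echo["structures"] = [list(asdict(s).values()) for s in config.structures]
        echo["pack_map"] = dict(config.pack_map)
        echo["pack_trajectories"] = {
            p: dict(t) for p, t in config.pack_trajectories.items()
        }
        echo["prey_rates"] = dict(config.prey_rates)
        path = directory / "config.yaml"
        path.write_text(yaml.safe_dump(echo, sort_keys=True), encoding="utf-8")
        paths["config"] = path
    return paths


def study_default_config(seed: int = 0) -> SimulationConfig:
    """Configuration mirroring the monitored study design.

    Six green bridges with four cameras each, monitored five years
    (2009/2010-2013/2014); four viaducts with camera counts matching their
    reported trap-day totals, monitored two years (2010/2011-2011/2012);
    the five packs mapped to their structures, with multi-year pack-size
    trajectories that decline in the north and partially recover in the
    southernmost pack.  Rates and group parameters are illustrative
    defaults (the detection process is not parameterized by the study).
    """
    structures = [
        StructureSpec("IB", "green_bridge", 4),
        StructureSpec("MG", "green_bridge", 4),
        StructureSpec("VAR", "green_bridge", 4),
        StructureSpec("OSM", "green_bridge", 4),
        StructureSpec("RO", "green_bridge", 4),
        StructureSpec("KON", "green_bridge", 4),
        StructureSpec("GRABA", "viaduct", 2),
        StructureSpec("SUV", "viaduct", 3),
        StructureSpec("MP", "viaduct", 1),
        StructureSpec("GRABARA", "viaduct", 4),
    ]
    pack_map = {
        "IB": "Saborsko",
        "MG": "Golo trlo",
        "VAR": "Golo trlo",
        "GRABA": "Golo trlo",
        "SUV": "Golo trlo",
        "MP": "Golo trlo",
        "GRABARA": "Juzni Velebit",
        "OSM": "Vucevica",
        "RO": "Mosor",
        "KON": "Mosor",
    }
    years = ["2009/2010", "2010/2011", "2011/2012", "2012/2013", "2013/2014"]

    def traj(sizes):
        return dict(zip(years, sizes))

    pack_trajectories = {
        "Saborsko": traj([3, 2, 0, 0, 0]),
        "Golo trlo": traj([5, 11, 3, 1, 1]),
        "Juzni Velebit": traj([4, 4, 2, 1, 1]),
        "Vucevica": traj([7, 8, 4, 2, 1]),
        "Mosor": traj([5, 4, 3, 2, 6]),
    }
    viaduct_years = years[1:3]
    return SimulationConfig(
        structures=structures,
        pack_map=pack_map,
        pack_trajectories=pack_trajectories,
        crossing_rate_per_wolf=0.01,
        mean_group_fraction=0.4,
        dwell_mean_s=90.0,
        trigger_delay_s=60.0,
        miss_prob=0.1,
        camera_detect_prob=0.8,
        prey_rates={
            "roe_deer": 0.9,
            "red_deer": 0.25,
            "wild_boar": 0.35,
            "other": 1.6,
        },
        structure_years={
            "GRABA": viaduct_years,
            "SUV": viaduct_years,
            "MP": viaduct_years,
            "GRABARA": viaduct_years,
        },
        seed=seed,
    )


def simulate_cull_effect_series(
    seed: int,
    n_years: int = 5,
    intercept: float = 60.0,
    cull_effect: float = 4.0,
    noise_sd: float = 5.0,
    cull: Sequence[int] | None = None,
    first_start_year: int = 2009,
    pack_id: str = "SIM",
):
    """Synthetic annual series with a designed negative legal-cull effect.

    Wolf events follow ``intercept - cull_effect * cull + noise`` (rounded,
    floored at zero); the other covariates (accidental casualties, domestic
    kills) are independent noise, so any significance they attain is a false
    positive.  Used for the parameter-recovery check on the regression
    battery.

    Returns
    -------
    (summaries, covariates)
        Per-year :class:`~crossingmon.trends.AnnualPackSummary` rows for one
        synthetic pack, and the aligned covariate table.
    """
    from .trends import AnnualPackSummary

    rng = np.random.default_rng(seed)
    years = [f"{first_start_year + i}/{first_start_year + i + 1}" for i in range(n_years)]
    if cull is None:
        cull = (10, 4, 12, 2, 5)[:n_years]
    if len(cull) != n_years:
        raise ValueError("cull series length must equal n_years")
    cull = np.asarray(cull, dtype=float)

    events = np.maximum(
        0, np.rint(intercept - cull_effect * cull + rng.normal(0, noise_sd, n_years))
    ).astype(int)

    def varied(low: int, high: int) -> np.ndarray:
        # covariates must vary across years to be regressable at all
        vals = rng.integers(low, high, n_years)
        while np.ptp(vals) == 0:
            vals = rng.integers(low, high, n_years)
        return vals

    prey = varied(30, 80)
    accidental = varied(3, 9)
    domestic = varied(20, 60)

    summaries = []
    for i, year in enumerate(years):
        n_wolf = int(events[i])
        minpack = 0 if n_wolf == 0 else max(1, int(round(1 + n_wolf / 12.0)))
        summaries.append(
            AnnualPackSummary(
                pack_id=pack_id,
                monitoring_year=year,
                n_events_total=n_wolf + int(prey[i]),
                n_events_wolf=n_wolf,
                n_events_prey=int(prey[i]),
                n_events_roe_deer=0,
                n_events_red_deer=0,
                n_events_wild_boar=int(prey[i]),
                minimal_pack_size=minpack,
                trap_days=1460,
            )
        )
    covariates = pd.DataFrame(
        {
            "monitoring_year": years,
            "legal_cull": cull.astype(int),
            "accidental": accidental,
            "domestic_killed": domestic,
        }
    )
    return summaries, covariates
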