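"""Covariate analysis: mortality/livestock data and the trend regressions.

The abundance indices (wolf events per year, minimal pack size) are
regressed on external covariates — prey event counts, livestock depredation,
and human-caused wolf mortality split into legal cull and accidental
casualties (vehicle collisions, poaching, poisoning, unknown).  The model is
simple linear regression y = a + b x fitted per covariate pair; reported
alongside the slope are r-squared, the adjusted r-squared
1 - (1 - r^2)(n - 1)/(n - 2) (which can be negative for no-signal fits), the
slope t statistic and its two-sided P value on n - 2 degrees of freedom.

Significance is flagged at two-sided P < 0.05 and no multiple-testing
correction is applied by default (``holm=True`` on the battery adds one).

Shaped in the statsmodels tradition: :class:`RegressionBattery` is a model
object built from data whose :meth:`~RegressionBattery.fit` returns a
:class:`BatteryResults` carrying the estimates and a ``summary()`` table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_half_up
from .trends import AnnualPackSummary, summaries_to_frame

__all__ = [
    "MORTALITY_CAUSES",
    "ACCIDENTAL_CAUSES",
    "MortalityRecord",
    "LivestockDamage",
    "RegressionResult",
    "AlignmentError",
    "DegenerateDesignError",
    "fit_ols",
    "RegressionBattery",
    "BatteryResults",
    "events_minpack_correlation",
    "partition_mortality",
    "MortalityShares",
    "livestock_damage_percent",
    "build_covariate_table",
    "read_mortality",
    "write_mortality",
    "read_livestock",
    "write_livestock",
    "pool_summaries",
]

MORTALITY_CAUSES = (
    "legal_cull",
    "vehicle_collision",
    "poaching",
    "poisoning",
    "unknown",
)

#: All causes of death other than the authorized harvest.
ACCIDENTAL_CAUSES = tuple(c for c in MORTALITY_CAUSES if c != "legal_cull")

SIGNIFICANCE_LEVEL = 0.05


class AlignmentError(ValueError):
    """Year mismatch between the abundance series and a covariate series."""


class DegenerateDesignError(ValueError):
    """Constant regressor or too few observations for a t test."""


@dataclass(frozen=True)
class MortalityRecord:
    """Wolf deaths in one county and monitoring year, by cause."""

    county: str
    monitoring_year: str
    cause: str
    n_wolves: int

    def __post_init__(self) -> None:
        if self.cause not in MORTALITY_CAUSES:
            raise ValueError(
                f"cause must be one of {MORTALITY_CAUSES}, got {self.cause!r}"
            )
        if self.n_wolves < 0:
            raise ValueError("n_wolves must be non-negative")


@dataclass(frozen=True)
class LivestockDamage:
    """Livestock killed by wolves vs. registered livestock, per county-year."""

    county: str
    monitoring_year: str
    n_killed: int
    n_registered: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_killed <= self.n_registered:
            raise ValueError(
                "n_killed must lie between 0 and n_registered "
                f"({self.n_killed} vs {self.n_registered})"
            )


@dataclass(frozen=True)
class RegressionResult:
    """One simple-linear-regression fit.

    ``p_two_sided`` is the two-sided P value of the slope t statistic with
    ``n - 2`` degrees of freedom.
    """

    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    t_slope: float
    p_two_sided: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_two_sided < SIGNIFICANCE_LEVEL

    def summary(self) -> str:
        return (
            f"slope={self.slope:.4g}  intercept={self.intercept:.4g}  "
            f"r2={self.r2:.3f}  adj_r2={self.adjusted_r2:.3f}  "
            f"t={self.t_slope:.2f}  P={self.p_two_sided:.3g}  n={self.n}"
            + ("  *" if self.significant else "")
        )


def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares fit of ``y = intercept + slope * x``.

    A constant response carries no signal: r-squared is undefined (zero
    total variance), so the fit degenerates to slope 0 with P = 1 rather
    than erroring — a flat minimal-pack-size series is a legitimate input.

    Raises
    ------
    DegenerateDesignError
        For fewer than 3 points or a constant regressor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise DegenerateDesignError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("regressor is constant; slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            r2=0.0,
            adjusted_r2=0.0,
            t_slope=0.0,
            p_two_sided=1.0,
            n=n,
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        t_slope=float(res.tvalues[1]),
        p_two_sided=float(res.pvalues[1]),
        n=n,
    )


def pool_summaries(
    summaries: Sequence[AnnualPackSummary], packs: Sequence[str]
) -> pd.DataFrame:
    """Pool a pack subset per monitoring year.

    Event counts are summed over the packs; the pooled minimal pack size is
    the maximum over packs (the largest single-event group seen anywhere in
    the subset that year).
    """
    frame = summaries_to_frame(list(summaries))
    missing = set(packs) - set(frame["pack_id"])
    if missing:
        raise AlignmentError(f"no summaries for packs {sorted(missing)}")
    sub = frame[frame["pack_id"].isin(set(packs))]
    pooled = (
        sub.groupby("monitoring_year")
        .agg(
            n_events_wolf=("n_events_wolf", "sum"),
            n_events_prey=("n_events_prey", "sum"),
            n_events_total=("n_events_total", "sum"),
            minimal_pack_size=("minimal_pack_size", "max"),
            trap_days=("trap_days", "sum"),
        )
        .reset_index()
        .sort_values("monitoring_year")
        .reset_index(drop=True)
    )
    return pooled


DEPENDENTS = ("n_events_wolf", "minimal_pack_size")
INDEPENDENTS = (
    "n_events_prey",
    "domestic_killed",
    "accidental",
    "legal_cull",
    "total_mortality",
)


class RegressionBattery:
    """The battery of abundance-vs-covariate regressions for a pack subset.

    Parameters
    ----------
    summaries
        Per-pack annual summaries (any packs; the subset in ``packs`` is
        pooled per year before fitting).
    covariates
        Table with a ``monitoring_year`` column plus covariate columns
        (``domestic_killed``, ``accidental``, ``legal_cull``; a
        ``total_mortality`` column is derived as accidental + legal cull
        when absent).  ``n_events_prey`` always comes from the summaries.
    packs
        Pack subset to pool (e.g. the two southern packs).
    lag
        Shift covariates this many monitoring years earlier relative to the
        abundance series (0 = same-year alignment).
    """

    def __init__(
        self,
        summaries: Sequence[AnnualPackSummary],
        covariates: pd.DataFrame,
        packs: Sequence[str],
        dependents: Sequence[str] = DEPENDENTS,
        independents: Sequence[str] = INDEPENDENTS,
        lag: int = 0,
    ):
        self.pooled = pool_summaries(summaries, packs)
        self.packs = tuple(packs)
        self.dependents = tuple(dependents)
        self.independents = tuple(independents)

        cov = covariates.copy()
        if "monitoring_year" not in cov.columns:
            raise AlignmentError("covariate table needs a monitoring_year column")
        if (
            "total_mortality" not in cov.columns
            and {"accidental", "legal_cull"} <= set(cov.columns)
        ):
            cov["total_mortality"] = cov["accidental"] + cov["legal_cull"]
        if lag:
            # covariate observed in year t aligns to the response in year
            # t + lag (e.g. cull in one season against events the next)
            order = sorted(cov["monitoring_year"])
            shift = dict(zip(order[: len(order) - lag], order[lag:]))
            cov["monitoring_year"] = cov["monitoring_year"].map(shift)
            cov = cov.dropna(subset=["monitoring_year"])

        years = list(self.pooled["monitoring_year"])
        cov_years = set(cov["monitoring_year"])
        missing = [y for y in years if y not in cov_years]
        if missing:
            raise AlignmentError(
                f"covariate table is missing monitoring years {missing}"
            )
        merged = self.pooled.merge(cov, on="monitoring_year", how="left")
        self.data = merged.sort_values("monitoring_year").reset_index(drop=True)

    @classmethod
    def from_frames(
        cls,
        summary_frame: pd.DataFrame,
        covariates: pd.DataFrame,
        packs: Sequence[str],
        **kwargs,
    ) -> "RegressionBattery":
        from .trends import frame_to_summaries

        return cls(frame_to_summaries(summary_frame), covariates, packs, **kwargs)

    def fit(self, holm: bool = False) -> "BatteryResults":
        """Fit one OLS per dependent x independent pair."""
        results: dict[tuple[str, str], RegressionResult] = {}
        for dep in self.dependents:
            for ind in self.independents:
                if ind not in self.data.columns:
                    raise AlignmentError(f"covariate column {ind!r} not found")
                results[(dep, ind)] = fit_ols(
                    self.data[ind].to_numpy(float),
                    self.data[dep].to_numpy(float),
                )
        return BatteryResults(results, self.packs, holm=holm)


class BatteryResults:
    """Fitted regression battery.

    ``table`` is the report: one row per (dependent, independent) pair with
    slope, adjusted r-squared, t, P and the significance flag.
    """

    def __init__(
        self,
        results: Mapping[tuple[str, str], RegressionResult],
        packs: Sequence[str],
        holm: bool = False,
    ):
        self.results = dict(results)
        self.packs = tuple(packs)
        self.holm = holm
        rows = []
        pvals = np.array([r.p_two_sided for r in self.results.values()])
        if holm:
            from statsmodels.stats.multitest import multipletests

            reject, p_adj, _, _ = multipletests(
                pvals, alpha=SIGNIFICANCE_LEVEL, method="holm"
            )
        for i, ((dep, ind), r) in enumerate(self.results.items()):
            p = float(p_adj[i]) if holm else r.p_two_sided
            rows.append(
                {
                    "dependent": dep,
                    "independent": ind,
                    "slope": r.slope,
                    "r2": r.r2,
                    "adjusted_r2": r.adjusted_r2,
                    "t": r.t_slope,
                    "p": p,
                    "n": r.n,
                    "significant": bool(
                        reject[i] if holm else r.significant
                    ),
                }
            )
        self.table = pd.DataFrame(rows)

    def __getitem__(self, key: tuple[str, str]) -> RegressionResult:
        return self.results[key]

    def summary(self) -> str:
        lines = [
            f"Abundance-covariate regression battery (packs {'+'.join(self.packs)})",
            f"{'dependent':<20}{'independent':<20}{'adj_r2':>8}{'t':>8}{'P':>8}",
        ]
        for (dep, ind), r in self.results.items():
            star = " *" if r.significant else ""
            lines.append(
                f"{dep:<20}{ind:<20}{r.adjusted_r2:>8.2f}{r.t_slope:>8.2f}"
                f"{r.p_two_sided:>8.2f}{star}"
            )
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def events_minpack_correlation(
    summaries: Sequence[AnnualPackSummary], packs: Sequence[str]
) -> RegressionResult:
    """Regress minimal pack size on wolf event count for a pooled pack subset.

    Checks the premise that more events reflect a larger pack: a positive,
    significant slope supports using event counts as an abundance index for
    that subset.
    """
    pooled = pool_summaries(summaries, packs)
    if len(pooled) < 3:
        raise DegenerateDesignError("need at least 3 monitoring years")
    return fit_ols(
        pooled["n_events_wolf"].to_numpy(float),
        pooled["minimal_pack_size"].to_numpy(float),
    )


@dataclass(frozen=True)
class MortalityShares:
    """Percent split of total wolf mortality, half-up rounded to 1 decimal."""

    legal_pct: float
    accidental_pct: float
    within_accidental: dict
    n_total: int


def partition_mortality(
    records: Iterable[MortalityRecord] | Mapping[str, int],
) -> MortalityShares:
    """Split total mortality into legal cull vs accidental casualties.

    Accepts mortality records or a ``cause -> count`` mapping.  Returns the
    two group percentages plus the within-accidental breakdown per cause,
    each half-up rounded to one decimal.  Groups sum to 100 up to rounding.
    """
    counts = dict.fromkeys(MORTALITY_CAUSES, 0)
    if isinstance(records, Mapping):
        for cause, n in records.items():
            if cause not in counts:
                raise ValueError(f"unknown cause {cause!r}")
            counts[cause] += int(n)
    else:
        for r in records:
            counts[r.cause] += r.n_wolves
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total mortality must be positive")
    legal = counts["legal_cull"]
    accidental = total - legal
    within = {}
    for cause in ACCIDENTAL_CAUSES:
        within[cause] = (
            round_half_up(100.0 * counts[cause] / accidental, 1)
            if accidental > 0
            else 0.0
        )
    return MortalityShares(
        legal_pct=round_half_up(100.0 * legal / total, 1),
        accidental_pct=round_half_up(100.0 * accidental / total, 1),
        within_accidental=within,
        n_total=total,
    )


def livestock_damage_percent(damage: LivestockDamage) -> float:
    """Percent of registered livestock killed by wolves in a county-year."""
    if damage.n_registered <= 0:
        raise ValueError("n_registered must be positive")
    return 100.0 * damage.n_killed / damage.n_registered


def build_covariate_table(
    mortality: Sequence[MortalityRecord],
    livestock: Sequence[LivestockDamage],
    counties: Sequence[str],
    years: Sequence[str],
) -> pd.DataFrame:
    """Per-year covariates for a county subset.

    Columns: ``monitoring_year, legal_cull, accidental, total_mortality,
    domestic_killed, livestock_pct`` — mortality and depredation summed over
    the counties, the damage percentage computed on the pooled registers.
    """
    counties = set(counties)
    rows = []
    for year in years:
        legal = sum(
            r.n_wolves
            for r in mortality
            if r.county in counties
            and r.monitoring_year == year
            and r.cause == "legal_cull"
        )
        accidental = sum(
            r.n_wolves
            for r in mortality
            if r.county in counties
            and r.monitoring_year == year
            and r.cause != "legal_cull"
        )
        killed = sum(
            d.n_killed
            for d in livestock
            if d.county in counties and d.monitoring_year == year
        )
        registered = sum(
            d.n_registered
            for d in livestock
            if d.county in counties and d.monitoring_year == year
        )
        rows.append(
            {
                "monitoring_year": year,
                "legal_cull": legal,
                "accidental": accidental,
                "total_mortality": legal + accidental,
                "domestic_killed": killed,
                "livestock_pct": (
                    100.0 * killed / registered if registered > 0 else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def read_mortality(path: str | Path) -> list[MortalityRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MortalityRecord(
                    county=row["county"],
                    monitoring_year=row["monitoring_year"],
                    cause=row["cause"],
                    n_wolves=int(row["n_wolves"]),
                )
            )
    return out


def write_mortality(records: Sequence[MortalityRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["county", "monitoring_year", "cause", "n_wolves"])
        for r in records:
            w.writerow([r.county, r.monitoring_year, r.cause, r.n_wolves])
    return path


def read_livestock(path: str | Path) -> list[LivestockDamage]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LivestockDamage(
                    county=row["county"],
                    monitoring_year=row["monitoring_year"],
                    n_killed=int(row["n_killed"]),
                    n_registered=int(row["n_registered"]),
                )
            )
    return out


def write_livestock(records: Sequence[LivestockDamage], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["county", "monitoring_year", "n_killed", "n_registered"])
        for r in records:
            w.writerow([r.county, r.monitoring_year, r.n_killed, r.n_registered])
    return path
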