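"""Per-capita (boundary-crosser) rates from fossil stratigraphic ranges.

Taxon ranges — first appearance datum (FAD) and last appearance datum
(LAD), both in Ma — are binned into a uniform grid of nonoverlapping
intervals.  Within each interval taxa fall into exactly one of Foote's four
categories:

====  ==========================================================
Nbt   range crosses both the bottom (older) and top (younger) edge
NbL   crosses the bottom edge, last appears within the interval
NFt   first appears within the interval, crosses the top edge
NFL   confined to the interval (singletons)
====  ==========================================================

from which the per-capita rates are

    q_hat = -ln(Nbt / (Nbt + NbL)) / dt     (extinction)
    p_hat = -ln(Nbt / (Nbt + NFt)) / dt     (origination)

Singletons are counted and reported but never enter the rate formulas.
Intervals where Nbt = 0 are flagged undefined and excluded from summaries.

Boundary convention (half-open intervals [older, younger)): a taxon crosses
an edge at age x iff FAD >= x and LAD < x for the bottom edge, and FAD > x
and LAD <= x for the top edge; a FAD exactly on an edge is credited to the
older interval.

The model-style entry point is :class:`PerCapitaRates`, whose ``fit()``
computes a rate series for each requested bin duration and summarizes them
as the across-duration average of per-duration medians (plus means and SDs).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FossilRangeTable",
    "IntervalGrid",
    "read_ranges_csv",
    "bin_ranges",
    "per_capita_rates",
    "summarize_series",
    "PerCapitaRates",
    "PerCapitaRatesResults",
]

PARAMS = ("p", "q", "r", "eps", "tau")
DEFAULT_DURATIONS = (0.5, 1.0, 2.5, 5.0)


@dataclass(frozen=True)
class FossilRangeTable:
    """Per-taxon first/last appearance ages in Ma (FAD >= LAD >= 0)."""

    taxon: np.ndarray
    fad: np.ndarray
    lad: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FossilRangeTable":
        cols = {c.lower(): c for c in df.columns}
        try:
            taxon = df[cols.get("taxon", df.columns[0])].to_numpy()
            fad = df[cols["fad_ma"]].to_numpy(dtype=float)
            lad = df[cols["lad_ma"]].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError("range table needs columns taxon,fad_ma,lad_ma") from exc
        return cls(taxon=taxon, fad=fad, lad=lad)

    def __post_init__(self):
        if len(self.taxon) != len(set(map(str, self.taxon))):
            raise ValueError("taxon ids must be unique")
        if np.any(self.lad < 0):
            raise ValueError("LAD ages must be nonnegative")
        if np.any(self.fad < self.lad):
            bad = np.asarray(self.taxon)[self.fad < self.lad]
            raise ValueError(f"FAD < LAD for taxa: {', '.join(map(str, bad[:5]))}")

    def __len__(self) -> int:
        return len(self.taxon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"taxon": self.taxon, "fad_ma": self.fad, "lad_ma": self.lad})


def read_ranges_csv(path_or_buffer) -> FossilRangeTable:
    return FossilRangeTable.from_frame(pd.read_csv(path_or_buffer, comment="#"))


@dataclass(frozen=True)
class IntervalGrid:
    """Uniform, contiguous bins from an origin age down to 0 Ma."""

    duration: float
    origin: float

    @classmethod
    def covering(cls, duration: float, max_age: float) -> "IntervalGrid":
        """Grid whose origin is the smallest multiple of ``duration`` >= max_age.

        Anchoring every grid at integer multiples of its bin duration keeps
        grids of different granularity comparable.
        """
        if duration <= 0:
            raise ValueError("bin duration must be positive")
        n = max(1, math.ceil(max_age / duration - 1e-9))
        return cls(duration=duration, origin=n * duration)

    @property
    def n_bins(self) -> int:
        return int(round(self.origin / self.duration))

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in descending order, from origin to 0."""
        return self.origin - self.duration * np.arange(self.n_bins + 1)

    def intervals(self) -> Iterable[Tuple[float, float]]:
        e = self.edges
        return list(zip(e[:-1], e[1:]))


def bin_ranges(ranges: FossilRangeTable, grid: IntervalGrid) -> pd.DataFrame:
    """Assign each taxon to one Foote category per overlapped interval.

    Returns a frame indexed by interval with columns
    ``interval_old, interval_young, n_bt, n_bl, n_ft, n_fl``.
    """
    fad, lad = ranges.fad, ranges.lad
    outside = fad > grid.origin + 1e-12
    if np.any(outside):
        bad = np.asarray(ranges.taxon)[outside]
        raise ValueError(
            f"range(s) older than grid origin {grid.origin}: {', '.join(map(str, bad[:5]))}"
        )
    rows = []
    for e_old, e_young in grid.intervals():
        bottom = (fad >= e_old) & (lad < e_old)
        top = (fad > e_young) & (lad <= e_young)
        fad_within = (fad < e_old) & (fad >= e_young)
        lad_within = (lad < e_old) & (lad > e_young)
        n_bt = int(np.sum(bottom & top))
        n_bl = int(np.sum(bottom & lad_within))
        n_ft = int(np.sum(fad_within & top))
        n_fl = int(np.sum(fad_within & lad_within))
        rows.append((e_old, e_young, n_bt, n_bl, n_ft, n_fl))
    return pd.DataFrame(
        rows, columns=["interval_old", "interval_young", "n_bt", "n_bl", "n_ft", "n_fl"]
    )


def per_capita_rates(counts: pd.DataFrame, duration: float) -> pd.DataFrame:
    """Foote's boundary-crosser estimators applied interval by interval.

    Intervals with ``n_bt == 0`` are flagged ``defined = False`` (the log
    ratios are undefined there) and carry NaN rates.
    """
    if duration <= 0:
        raise ValueError("bin duration must be positive")
    for col in ("n_bt", "n_bl", "n_ft"):
        if np.any(counts[col].to_numpy() < 0):
            raise ValueError(f"negative counts in column {col}")
    n_bt = counts["n_bt"].to_numpy(dtype=float)
    n_bl = counts["n_bl"].to_numpy(dtype=float)
    n_ft = counts["n_ft"].to_numpy(dtype=float)
    defined = n_bt > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        q = -np.log(n_bt / (n_bt + n_bl)) / duration
        p = -np.log(n_bt / (n_bt + n_ft)) / duration
    p[~defined] = np.nan
    q[~defined] = np.nan
    out = counts.copy()
    out["p"] = p
    out["q"] = q
    out["r"] = p - q
    with np.errstate(divide="ignore", invalid="ignore"):
        out["eps"] = np.where(p > 0, q / p, np.nan)
    out["tau"] = p + q
    out["defined"] = defined & np.isfinite(out["eps"].to_numpy())
    return out


def summarize_series(series: pd.DataFrame) -> pd.DataFrame:
    """Median, mean and SD of each rate parameter over defined intervals."""
    defined = series[series["defined"]]
    if defined.empty:
        raise ValueError("no defined intervals to summarize")
    rows = {}
    for par in PARAMS:
        vals = defined[par].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        rows[par] = {
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return pd.DataFrame(rows).T[["median", "mean", "sd"]]


class PerCapitaRates:
    """Boundary-crosser rate model over one or more bin granularities.

    Parameters
    ----------
    ranges : FossilRangeTable or DataFrame
        First/last appearance ages per taxon.
    durations : sequence of float
        Bin durations in Myr (default 0.5, 1.0, 2.5 and 5.0).
    """

    def __init__(self, ranges, durations: Sequence[float] = DEFAULT_DURATIONS):
        if isinstance(ranges, pd.DataFrame):
            ranges = FossilRangeTable.from_frame(ranges)
        self.ranges = ranges
        self.durations = tuple(float(d) for d in durations)
        if not self.durations:
            raise ValueError("need at least one bin duration")

    def fit(self) -> "PerCapitaRatesResults":
        max_age = float(np.max(self.ranges.fad))
        series: Dict[float, pd.DataFrame] = {}
        for dt in self.durations:
            grid = IntervalGrid.covering(dt, max_age)
            counts = bin_ranges(self.ranges, grid)
            ser = per_capita_rates(counts, dt)
            n_undef = int((~ser["defined"]).sum())
            if n_undef:
                warnings.warn(
                    f"{n_undef} of {len(ser)} intervals undefined at dt={dt} Myr "
                    "(no boundary crossers); excluded from summaries",
                    stacklevel=2,
                )
            series[dt] = ser
        return PerCapitaRatesResults(self, series)


class PerCapitaRatesResults:
    """Per-granularity rate series plus cross-granularity summaries."""

    def __init__(self, model: PerCapitaRates, series: Dict[float, pd.DataFrame]):
        self.model = model
        self._series = series
        per_dt = {dt: summarize_series(ser) for dt, ser in series.items()}
        self._per_duration_summaries = per_dt
        # Canonical statistic: across-duration mean of per-duration medians
        # (likewise for means and SDs).
        self.summary_table = (
            pd.concat(per_dt.values()).groupby(level=0).mean().loc[list(PARAMS)]
        )

    def series(self, duration: Optional[float] = None) -> pd.DataFrame:
        if duration is None:
            frames = []
            for dt, ser in self._series.items():
                f = ser.copy()
                f.insert(0, "granularity", dt)
                frames.append(f)
            return pd.concat(frames, ignore_index=True)
        return self._series[float(duration)]

    def summary_by_duration(self, duration: float) -> pd.DataFrame:
        return self._per_duration_summaries[float(duration)]

    @property
    def epsilon(self) -> float:
        """Relative extinction: mean across granularities of per-granularity medians."""
        return float(self.summary_table.loc["eps", "median"])

    def parameter(self, name: str, stat: str = "median") -> float:
        return float(self.summary_table.loc[name, stat])

    def summary(self) -> str:
        lines = [
            "Per-capita (boundary-crosser) rates",
            f"  taxa: {len(self.model.ranges)}   bin durations (Myr): "
            + ", ".join(f"{d:g}" for d in self.model.durations),
            "  averages of per-granularity statistics across bin sizes:",
            self.summary_table.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        block = {
            par: {k: float(v) for k, v in self.summary_table.loc[par].items()}
            for par in PARAMS
        }
        return json.dumps(
            {"durations_myr": list(self.model.durations), "summary": block}, indent=2
        )
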