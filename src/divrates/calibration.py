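"""Fossil calibration bounds from ghost-lineage or penultimate-distance times.

Given the first occurrences of two sister lineages (or the earliest and
second-earliest occurrences of one lineage), the gap G between them is an
estimate of unobserved history.  A node-age prior is built as an offset
lognormal: offset at the older occurrence, real-space mean G/2 above the
offset and real-space standard deviation 1.814 Myr; the 5% and 95%
quantiles of this distribution give the minimum and maximum age bounds for
the calibrated node.

"mean" and "standard deviation" are interpreted as real-space moments and
converted by moment matching (sigma^2 = ln(1 + s^2/m^2),
mu = ln m - sigma^2/2); pass ``parameterization="log_params"`` to treat them
as the log-scale parameters instead.

Only bound construction is done here; the bounds are emitted as a
treePL-style plain-text configuration block for consumption by a dating
tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .trees import TimeTree

__all__ = [
    "DEFAULT_SD_MYR",
    "CalibrationRecord",
    "ghost_lineage_time",
    "lognormal_bounds",
    "calibrate_record",
    "read_calibrations_csv",
    "build_calibration_table",
    "bounds_frame",
]

DEFAULT_SD_MYR = 1.814


@dataclass
class CalibrationRecord:
    """One node calibration defined by a tip pair and two occurrence ages."""

    taxon_a: str
    taxon_b: str
    age_a_ma: float
    age_b_ma: float
    kind: str = "auto"  # auto | min_only | min_max
    name: Optional[str] = None

    # filled by calibrate_record()
    ghost_time: Optional[float] = None
    offset: Optional[float] = None
    min_bound: Optional[float] = None
    max_bound: Optional[float] = None

    @property
    def label(self) -> str:
        return self.name or f"{self.taxon_a}_{self.taxon_b}"


def ghost_lineage_time(fad_a: float, fad_b: float) -> Tuple[float, float]:
    """Ghost-lineage (or penultimate-distance) time and offset.

    G = |fad_a - fad_b|; the offset is the older of the two occurrences.
    Symmetric in its arguments.
    """
    if fad_a < 0 or fad_b < 0:
        raise ValueError("occurrence ages must be nonnegative")
    return abs(fad_a - fad_b), max(fad_a, fad_b)


def lognormal_bounds(
    ghost_time: float,
    offset: float,
    sd: float = DEFAULT_SD_MYR,
    q_lo: float = 0.05,
    q_hi: float = 0.95,
    parameterization: str = "real_moments",
) -> Tuple[float, float]:
    """Min/max node-age bounds from the offset lognormal prior.

    Parameters
    ----------
    ghost_time : float
        G in Myr; the distribution's real-space mean is G/2 above the offset.
    offset : float
        Older first occurrence, Ma.
    sd : float
        Real-space standard deviation in Myr (default 1.814).
    q_lo, q_hi : float
        Quantiles used as minimum and maximum bounds.
    parameterization : str
        "real_moments" (moment matching, default) or "log_params"
        (mean/sd applied on the log scale directly).

    Raises
    ------
    ValueError for G <= 0 (use kind="min_only" at the record level).
    """
    if ghost_time <= 0:
        raise ValueError("ghost time must be positive for a two-sided bound")
    if sd <= 0:
        raise ValueError("sd must be positive")
    m = ghost_time / 2.0
    if parameterization == "real_moments":
        sigma2 = math.log1p((sd / m) ** 2)
        sigma = math.sqrt(sigma2)
        mu = math.log(m) - sigma2 / 2.0
    elif parameterization == "log_params":
        mu, sigma = m, sd
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    lo, hi = dist.ppf(q_lo), dist.ppf(q_hi)
    return offset + lo, offset + hi


def calibrate_record(
    record: CalibrationRecord,
    sd: float = DEFAULT_SD_MYR,
    q_lo: float = 0.05,
    q_hi: float = 0.95,
    parameterization: str = "real_moments",
) -> CalibrationRecord:
    """Fill in ghost time, offset and bounds; degenerate G=0 becomes min_only."""
    g, offset = ghost_lineage_time(record.age_a_ma, record.age_b_ma)
    record.ghost_time, record.offset = g, offset
    if record.kind == "min_only" or g == 0:
        record.kind = "min_only"
        record.min_bound, record.max_bound = offset, None
        return record
    record.kind = "min_max"
    record.min_bound, record.max_bound = lognormal_bounds(
        g, offset, sd=sd, q_lo=q_lo, q_hi=q_hi, parameterization=parameterization
    )
    return record


def read_calibrations_csv(path_or_buffer) -> List[CalibrationRecord]:
    df = pd.read_csv(path_or_buffer, comment="#")
    needed = {"taxon_a", "taxon_b", "age_a_ma", "age_b_ma"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing column(s): {', '.join(sorted(missing))}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CalibrationRecord(
                taxon_a=str(row.taxon_a),
                taxon_b=str(row.taxon_b),
                age_a_ma=float(row.age_a_ma),
                age_b_ma=float(row.age_b_ma),
                kind=str(getattr(row, "kind", "auto") or "auto"),
                name=str(getattr(row, "name", "") or "") or None,
            )
        )
    return records


def build_calibration_table(
    records: Sequence[CalibrationRecord],
    tree: TimeTree,
    sd: float = DEFAULT_SD_MYR,
    q_lo: float = 0.05,
    q_hi: float = 0.95,
    parameterization: str = "real_moments",
) -> str:
    """Emit a treePL-style configuration block, one mrca/min/max stanza per record.

    Every record's tip pair must resolve to a node of ``tree``; min-only
    records omit the ``max`` line.
    """
    tips = set(tree.tip_labels)
    missing = sorted(
        {t for rec in records for t in (rec.taxon_a, rec.taxon_b) if t not in tips}
    )
    if missing:
        raise KeyError(f"calibration tips not in tree: {', '.join(missing)}")
    lines = ["# node calibrations (ages in Ma)"]
    for rec in records:
        rec = calibrate_record(
            rec, sd=sd, q_lo=q_lo, q_hi=q_hi, parameterization=parameterization
        )
        tree.mrca([rec.taxon_a, rec.taxon_b])  # existence check
        lines.append(f"mrca = {rec.label} {rec.taxon_a} {rec.taxon_b}")
        lines.append(f"min = {rec.label} {rec.min_bound:.6f}")
        if rec.kind == "min_max":
            lines.append(f"max = {rec.label} {rec.max_bound:.6f}")
    return "\n".join(lines) + "\n"


def bounds_frame(
    records: Sequence[CalibrationRecord], sd: float = DEFAULT_SD_MYR, **kwargs
) -> pd.DataFrame:
    """Tidy table of computed bounds for a record list."""
    rows = []
    for rec in records:
        rec = calibrate_record(rec, sd=sd, **kwargs)
        rows.append(
            {
                "name": rec.label,
                "taxon_a": rec.taxon_a,
                "taxon_b": rec.taxon_b,
                "ghost_time_myr": rec.ghost_time,
                "offset_ma": rec.offset,
                "kind": rec.kind,
                "min_ma": rec.min_bound,
                "max_ma": rec.max_bound,
            }
        )
    return pd.DataFrame(rows)
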