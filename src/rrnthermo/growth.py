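"""Growth-curve analysis: OD-to-cell conversion, interval growth rates, and
cardinal-temperature determination.

Specific growth rates are computed between consecutive observations under an
exponential-growth assumption,

    mu (1/h) = (ln N_t2 - ln N_t1) / (t2 - t1),

where N is cell density obtained from optical density through a
linear-through-origin cell-number factor (cells/ml per OD660 unit).  Because
the factor cancels inside the log ratio, mu is identical whether computed on
OD or on cell densities — kept as a checked invariant.  The maximum growth
rate mu_max of a curve is the largest interval rate; cardinal temperatures
(T_min, T_opt, T_max) are read off the tested temperature grid: T_opt is the
argmax of mean mu_max, T_min/T_max the extreme tested temperatures whose mean
mu_max exceeds a growth-call threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GrowthAnalysisError


@dataclass(frozen=True)
class GrowthCurve:
    """OD660 time series for one strain x temperature x replicate."""

    strain: str
    temperature: float
    replicate: int
    observations: tuple[tuple[float, float], ...]  # (time h, od660)

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise GrowthAnalysisError("growth curve needs >=2 observations")
        times = [t for t, _ in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise GrowthAnalysisError("observation times must be strictly increasing")
        if any(od < 0 for _, od in self.observations):
            raise GrowthAnalysisError("OD660 must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.observations])

    @property
    def od(self) -> np.ndarray:
        return np.asarray([o for _, o in self.observations])


@dataclass(frozen=True)
class CellFactor:
    """Cells/ml per OD660 unit, from a through-origin fit of count pairs."""

    factor: float
    fit_r_squared: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise GrowthAnalysisError("cell factor must be positive")


# The conversion factor determined for H. hispanica by epifluorescence
# counting: 2.1e9 cells/ml per OD660 unit.
DEFAULT_CELL_FACTOR = CellFactor(factor=2.1e9, fit_r_squared=float("nan"), n_pairs=0)


@dataclass(frozen=True)
class IntervalRate:
    """Growth rate over one consecutive-observation interval."""

    t_mid: float
    mu: float | None  # None where a density was <= 0 (flagged gap)


@dataclass
class GrowthRateProfile:
    """Interval growth rates and mu_max for one curve."""

    curve: GrowthCurve
    intervals: list[IntervalRate]

    @property
    def mu_values(self) -> list[float]:
        return [iv.mu for iv in self.intervals if iv.mu is not None]

    @property
    def mu_max(self) -> float:
        return max(self.mu_values)


@dataclass(frozen=True)
class CardinalTemps:
    """Cardinal temperatures called on the tested temperature grid."""

    t_min: float
    t_opt: float
    t_max: float
    growth_threshold: float

    def __post_init__(self) -> None:
        if not self.t_min <= self.t_opt <= self.t_max:
            raise GrowthAnalysisError("cardinal temperatures out of order")


def fit_cell_factor(pairs: Sequence[tuple[float, float]]) -> CellFactor:
    """Least-squares slope of cell counts versus OD, constrained through origin.

    ``pairs`` are (od660, cells/ml) with od > 0 and counts >= 0; at least 3
    pairs are required.  r-squared is reported for the through-origin model
    (1 - SS_res / SS_tot about zero).
    """
    if len(pairs) < 3:
        raise GrowthAnalysisError("need >=3 OD/count pairs")
    od = np.asarray([p[0] for p in pairs], dtype=float)
    cells = np.asarray([p[1] for p in pairs], dtype=float)
    if (od <= 0).any():
        raise GrowthAnalysisError("OD values must be positive")
    if (cells < 0).any():
        raise GrowthAnalysisError("cell counts must be non-negative")
    slope = float(od @ cells / (od @ od))
    ss_res = float(((cells - slope * od) ** 2).sum())
    ss_tot = float((cells**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CellFactor(factor=slope, fit_r_squared=r2, n_pairs=len(pairs))


def od_to_cells(od660: float, factor: CellFactor) -> float:
    """Convert an OD660 reading to cell density (cells/ml)."""
    if od660 < 0:
        raise GrowthAnalysisError("OD660 must be >= 0")
    return od660 * factor.factor


def interval_growth_rates(
    curve: GrowthCurve, factor: CellFactor = DEFAULT_CELL_FACTOR
) -> GrowthRateProfile:
    """Per-interval specific growth rates mu and mu_max for one curve.

    Intervals where either density is zero (or negative) are flagged as gaps
    rather than producing infinities; if no interval is usable an error is
    raised.  Negative rates (death/lag) are kept in the profile but are only
    selected as mu_max when every usable interval is negative.
    """
    intervals: list[IntervalRate] = []
    obs = curve.observations
    for (t1, od1), (t2, od2) in zip(obs, obs[1:]):
        t_mid = 0.5 * (t1 + t2)
        if od1 <= 0 or od2 <= 0:
            intervals.append(IntervalRate(t_mid=t_mid, mu=None))
            continue
        n1 = od_to_cells(od1, factor)
        n2 = od_to_cells(od2, factor)
        mu = (math.log(n2) - math.log(n1)) / (t2 - t1)
        intervals.append(IntervalRate(t_mid=t_mid, mu=mu))
    profile = GrowthRateProfile(curve=curve, intervals=intervals)
    if not profile.mu_values:
        raise GrowthAnalysisError(
            f"curve {curve.strain}/{curve.temperature}/{curve.replicate}: "
            "no usable intervals"
        )
    return profile


def mu_max_by_temperature(
    profiles: Sequence[GrowthRateProfile],
) -> pd.DataFrame:
    """Mean +/- sd of mu_max per temperature across replicates."""
    df = pd.DataFrame(
        {
            "strain": [p.curve.strain for p in profiles],
            "temperature": [p.curve.temperature for p in profiles],
            "replicate": [p.curve.replicate for p in profiles],
            "mu_max": [p.mu_max for p in profiles],
        }
    )
    out = (
        df.groupby(["strain", "temperature"], as_index=False)["mu_max"]
        .agg(mean_mu_max="mean", sd_mu_max=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .sort_values(["strain", "temperature"], ignore_index=True)
    )
    return out


def cardinal_temperatures(
    mu_by_temp: Mapping[float, float],
    growth_threshold: float = 0.005,
) -> CardinalTemps:
    """Call (T_min, T_opt, T_max) from mean mu_max per tested temperature.

    T_opt is the temperature with the highest mean mu_max (ties resolved to
    the lower temperature); T_min and T_max are the lowest and highest tested
    temperatures with mean mu_max above ``growth_threshold`` (default
    0.005/h, well below any plausibly measurable growth).  No interpolation
    is performed: all three are members of the tested grid.
    """
    if len(mu_by_temp) < 2:
        raise GrowthAnalysisError("need >=2 tested temperatures")
    temps = sorted(mu_by_temp)
    growing = [t for t in temps if mu_by_temp[t] > growth_threshold]
    if not growing:
        raise GrowthAnalysisError(
            f"no growth: no temperature with mean mu_max > {growth_threshold}/h"
        )
    t_opt = max(growing, key=lambda t: (mu_by_temp[t], -t))
    return CardinalTemps(
        t_min=min(growing),
        t_opt=t_opt,
        t_max=max(growing),
        growth_threshold=growth_threshold,
    )


def read_growth_table(path) -> list[GrowthCurve]:
    """Read a delimited growth table (strain, temperature, replicate, time_h,
    od660) into curves, one per strain x temperature x replicate."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    curves = []
    for (strain, temp, rep), grp in df.groupby(["strain", "temperature", "replicate"]):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                temperature=float(temp),
                replicate=int(rep),
                observations=tuple(zip(grp["time_h"].astype(float), grp["od660"].astype(float))),
            )
        )
    return curves


def write_growth_table(curves: Sequence[GrowthCurve], path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = [
        {
            "strain": c.strain,
            "temperature": c.temperature,
            "replicate": c.replicate,
            "time_h": t,
            "od660": od,
        }
        for c in curves
        for t, od in c.observations
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
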