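"""Catalytic efficiency and relative activity from plate-reader progress curves.

The deacetylation assay follows product fluorescence versus time at several
enzyme concentrations and one substrate concentration far below saturation.
In that regime the initial rate is v0 = (kcat/KM)[E][S] (times an arbitrary
fluorescence conversion factor), so:

1. ``initial_rates``    -- v0 per enzyme concentration as the ordinary
   least-squares slope of fluorescence vs time (a.u./min), with slope
   standard error and an R^2 linearity diagnostic;
2. ``efficiency_slope`` -- a quantity proportional to kcat/KM as the slope
   of v0 vs [E] (intercept left free and reported);
3. ``relative_activity`` -- a mutant's efficiency as a percentage of
   wild-type.  Because everything is a ratio, no fluorescence calibration
   is needed and arbitrary units suffice.

The error on the relative activity is an r.m.s.d. over jackknifed
sub-assays: the full pipeline is re-run leaving out one enzyme
concentration at a time and one time point at a time (in both variants
simultaneously), and the root-mean-square deviation of the re-computed
ratios about the full-data value is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateTimeCourse",
    "RateResult",
    "initial_rates",
    "efficiency_slope",
    "rate_result",
    "relative_activity",
]


@dataclass
class PlateTimeCourse:
    """Fluorescence progress curves for one variant.

    ``fluorescence[i, j]`` corresponds to ``enzyme_uM[i]`` and
    ``time_min[j]``.
    """

    variant: str
    enzyme_uM: np.ndarray
    time_min: np.ndarray
    fluorescence: np.ndarray  # a.u., shape (n_conc, n_time)
    substrate_uM: float = 200.0

    def __post_init__(self) -> None:
        self.enzyme_uM = np.asarray(self.enzyme_uM, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.shape != (len(self.enzyme_uM), len(self.time_min)):
            raise ValueError("fluorescence must be (n_conc, n_time)")
        if len(self.enzyme_uM) < 2:
            raise ValueError("need at least two enzyme concentrations")
        if len(self.time_min) < 3:
            raise ValueError("need at least three time points")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variant: str) -> "PlateTimeCourse":
        """Build from a tidy table (variant, enzyme_uM, time_min, fluorescence)."""
        sub = frame[frame["variant"] == variant]
        if sub.empty:
            raise ValueError(f"variant {variant!r} not present in table")
        pivot = sub.pivot_table(
            index="enzyme_uM", columns="time_min", values="fluorescence"
        ).sort_index()
        substrate = float(sub["substrate_uM"].iloc[0]) if "substrate_uM" in sub else 200.0
        return cls(
            variant=variant,
            enzyme_uM=pivot.index.to_numpy(),
            time_min=pivot.columns.to_numpy(dtype=float),
            fluorescence=pivot.to_numpy(),
            substrate_uM=substrate,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.enzyme_uM):
            for j, t in enumerate(self.time_min):
                rows.append(
                    {
                        "variant": self.variant,
                        "enzyme_uM": e,
                        "time_min": t,
                        "fluorescence": self.fluorescence[i, j],
                        "substrate_uM": self.substrate_uM,
                    }
                )
        return pd.DataFrame(rows)

    def subset(self, conc_mask=None, time_mask=None) -> "PlateTimeCourse":
        ci = np.arange(len(self.enzyme_uM)) if conc_mask is None else np.flatnonzero(conc_mask)
        ti = np.arange(len(self.time_min)) if time_mask is None else np.flatnonzero(time_mask)
        return PlateTimeCourse(
            variant=self.variant,
            enzyme_uM=self.enzyme_uM[ci],
            time_min=self.time_min[ti],
            fluorescence=self.fluorescence[np.ix_(ci, ti)],
            substrate_uM=self.substrate_uM,
        )


@dataclass
class RateResult:
    """Initial rates and the catalytic-efficiency slope for one variant."""

    variant: str
    v0: np.ndarray  # a.u./min per concentration
    v0_stderr: np.ndarray
    v0_r2: np.ndarray
    enzyme_uM: np.ndarray
    slope: float  # a.u./min/uM, proportional to kcat/KM
    slope_stderr: float
    intercept: float
    relative_percent: float | None = None
    relative_rmsd: float | None = None


def initial_rates(tc: PlateTimeCourse, blank: float | None = None):
    """Per-concentration initial rates v0 (OLS slope of F vs t).

    ``blank`` optionally subtracts a constant background fluorescence first
    (a pure offset does not change slopes; the flag exists for workflows
    whose blank varies between plates).  Concentrations with fewer than
    three finite points get NaN rates.  Returns (v0, stderr, r2) arrays.
    """
    f = tc.fluorescence - (blank or 0.0)
    n_conc = len(tc.enzyme_uM)
    v0 = np.full(n_conc, np.nan)
    se = np.full(n_conc, np.nan)
    r2 = np.full(n_conc, np.nan)
    for i in range(n_conc):
        ok = np.isfinite(f[i])
        if ok.sum() < 3:
            continue
        res = stats.linregress(tc.time_min[ok], f[i, ok])
        v0[i] = res.slope
        se[i] = res.stderr
        r2[i] = res.rvalue**2
    return v0, se, r2


def efficiency_slope(v0: Sequence[float], enzyme_uM: Sequence[float]):
    """Slope of v0 versus [E] (proportional to kcat/KM); intercept free.

    Returns (slope, stderr, intercept).  Requires v0 defined for at least
    two concentrations.
    """
    v0 = np.asarray(v0, dtype=float)
    e = np.asarray(enzyme_uM, dtype=float)
    ok = np.isfinite(v0)
    if ok.sum() < 2:
        raise ValueError("need initial rates at >= 2 enzyme concentrations")
    res = stats.linregress(e[ok], v0[ok])
    return float(res.slope), float(res.stderr), float(res.intercept)


def rate_result(tc: PlateTimeCourse, blank: float | None = None) -> RateResult:
    """Full per-variant rate analysis: v0 per concentration + efficiency slope."""
    v0, se, r2 = initial_rates(tc, blank=blank)
    slope, slope_se, intercept = efficiency_slope(v0, tc.enzyme_uM)
    return RateResult(
        variant=tc.variant,
        v0=v0,
        v0_stderr=se,
        v0_r2=r2,
        enzyme_uM=tc.enzyme_uM,
        slope=slope,
        slope_stderr=slope_se,
        intercept=intercept,
    )


def relative_activity(
    mutant: PlateTimeCourse,
    wt: PlateTimeCourse,
    blank: float | None = None,
) -> RateResult:
    """Mutant catalytic efficiency as a percentage of wild-type, with r.m.s.d.

    The percentage is 100 * slope_mut / slope_wt on the full data.  The
    r.m.s.d. error re-runs the pipeline on jackknifed sub-assays (leaving
    out one enzyme concentration, then one time point, in both variants)
    and takes the root-mean-square deviation of the sub-assay ratios about
    the full-data ratio.  Requires a positive wild-type slope.
    """
    full_mut = rate_result(mutant, blank=blank)
    full_wt = rate_result(wt, blank=blank)
    if not full_wt.slope > 0:
        raise ValueError("wild-type efficiency slope must be positive")
    ratio = 100.0 * full_mut.slope / full_wt.slope

    deviations = []
    n_conc = len(wt.enzyme_uM)
    n_time = len(wt.time_min)
    for i in range(n_conc):
        mask = np.ones(n_conc, bool)
        mask[i] = False
        if mask.sum() < 2:
            continue
        r = _sub_ratio(mutant.subset(conc_mask=mask), wt.subset(conc_mask=mask), blank)
        if r is not None:
            deviations.append(r - ratio)
    for j in range(n_time):
        mask = np.ones(n_time, bool)
        mask[j] = False
        if mask.sum() < 3:
            continue
        r = _sub_ratio(mutant.subset(time_mask=mask), wt.subset(time_mask=mask), blank)
        if r is not None:
            deviations.append(r - ratio)
    rmsd = float(np.sqrt(np.mean(np.square(deviations)))) if deviations else np.nan

    full_mut.relative_percent = float(ratio)
    full_mut.relative_rmsd = rmsd
    return full_mut


def _sub_ratio(mut_sub, wt_sub, blank):
    try:
        m = rate_result(mut_sub, blank=blank)
        w = rate_result(wt_sub, blank=blank)
    except ValueError:
        return None
    if not w.slope > 0:
        return None
    return 100.0 * m.slope / w.slope
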