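"""Inactive-state populations from fast-exchange peak positions.

When a variant interconverts rapidly (on the NMR time-scale) between the
active state and an inactive, inhibitor-bound-like state, each methyl
cross-peak sits at the population-weighted average of the two endpoint
positions.  The inactive-state fraction is therefore recovered per reporter
site by orthogonal projection of the variant peak onto the straight line
(the exchange axis) connecting the free and bound endpoint peaks:

    p_i = (x_var - x_free) . (x_bound - x_free) / |x_bound - x_free|^2

with peak positions expressed in scaled coordinates (dH/cH, dC/cC using the
per-class dCS normalisation constants) so the two axes are commensurate.
The component of the displacement perpendicular to the axis (the orthogonal
residual) measures how well the two-endpoint picture describes the variant.
Per-site fractions are combined across reporters (default: unweighted mean
over {I45, I56, I284}) and deliberately not clipped to [0, 1] so that
pathological variants remain visible.

The combined fractions are finally related to relative enzymatic activity
through the straight line connecting the fully active (p = 0) and fully
inactive (p = 1) endpoints, with the scatter of a variant cohort about that
line summarised as an r.m.s.d. in activity percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .csp import DELTA_CS_CONSTANTS, PeakList, classify_site

__all__ = [
    "DEFAULT_REPORTERS",
    "StateEndpoints",
    "PopulationEstimate",
    "project_population",
    "activity_population_line",
    "rmsd_about_line",
]

DEFAULT_REPORTERS = ("I45", "I56", "I284")


@dataclass(frozen=True)
class StateEndpoints:
    """Free- and bound-state peak positions per reporter site.

    Positions are (dH, dC) in ppm.  Every reporter must have distinct
    endpoints (the projection axis would otherwise be degenerate).
    """

    free: Mapping[str, tuple[float, float]]
    bound: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(self.free) ^ set(self.bound)
        if missing:
            raise ValueError(f"endpoints incomplete for sites {sorted(missing)}")

    @classmethod
    def from_peaklists(
        cls, free: PeakList, bound: PeakList, reporters: Sequence[str] = DEFAULT_REPORTERS
    ) -> "StateEndpoints":
        shared = [s for s in reporters if s in free and s in bound]
        return cls(
            free={s: (free[s].dh, free[s].dc) for s in shared},
            bound={s: (bound[s].dh, bound[s].dc) for s in shared},
        )


@dataclass
class PopulationEstimate:
    """Per-site and combined inactive-state fractions for one variant."""

    variant: str
    per_site: dict[str, float]
    residual: dict[str, float]  # orthogonal distance in scaled shift units
    combined: float
    spread: float  # SD over reporters
    out_of_range: bool
    skipped_sites: list[str] = field(default_factory=list)
    scaling: str = "normalised"
    combine: str = "mean"


def _scaled(site: str, pos: tuple[float, float], scaling: str,
            constants: Mapping[str, tuple[float, float]] | None) -> np.ndarray:
    if scaling == "raw":
        return np.asarray(pos, dtype=float)
    table = dict(DELTA_CS_CONSTANTS)
    if constants:
        table.update(constants)
    ch, cc = table[classify_site(site)]
    return np.array([pos[0] / ch, pos[1] / cc])


def project_population(
    endpoints: StateEndpoints,
    variant_peaks: PeakList,
    variant: str = "",
    scaling: str = "normalised",
    combine: str = "mean",
    constants: Mapping[str, tuple[float, float]] | None = None,
) -> PopulationEstimate:
    """Project variant peaks onto the free-to-bound exchange axis.

    ``scaling`` is ``"normalised"`` (dCS constants; default) or ``"raw"``
    (plain ppm).  ``combine`` is ``"mean"`` (default), ``"median"`` or
    ``"weighted"`` (inverse-variance by axis length: longer axes localise
    the projection better).  Sites with a degenerate axis are skipped with
    a warning entry; having no usable site is an error.  The combined
    fraction is flagged ``out_of_range`` outside [-0.2, 1.2].
    """
    if scaling not in ("normalised", "raw"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if combine not in ("mean", "median", "weighted"):
        raise ValueError(f"unknown combine rule {combine!r}")

    per_site: dict[str, float] = {}
    residual: dict[str, float] = {}
    axis_len2: dict[str, float] = {}
    skipped: list[str] = []
    for site in endpoints.free:
        if site not in variant_peaks:
            continue
        x_free = _scaled(site, endpoints.free[site], scaling, constants)
        x_bound = _scaled(site, endpoints.bound[site], scaling, constants)
        peak = variant_peaks[site]
        x_var = _scaled(site, (peak.dh, peak.dc), scaling, constants)
        axis = x_bound - x_free
        norm2 = float(axis @ axis)
        if norm2 < 1e-12:
            skipped.append(site)
            continue
        disp = x_var - x_free
        p_i = float(disp @ axis) / norm2
        per_site[site] = p_i
        residual[site] = float(np.linalg.norm(disp - p_i * axis))
        axis_len2[site] = norm2
    if not per_site:
        raise ValueError(
            f"no usable reporter site for variant {variant!r} "
            f"(skipped: {skipped or 'none present'})"
        )

    vals = np.array(list(per_site.values()))
    if combine == "mean":
        combined = float(vals.mean())
    elif combine == "median":
        combined = float(np.median(vals))
    else:
        w = np.array([axis_len2[s] for s in per_site])
        combined = float(np.average(vals, weights=w))
    spread = float(vals.std(ddof=0))
    return PopulationEstimate(
        variant=variant,
        per_site=per_site,
        residual=residual,
        combined=combined,
        spread=spread,
        out_of_range=not (-0.2 <= combined <= 1.2),
        skipped_sites=skipped,
        scaling=scaling,
        combine=combine,
    )


@dataclass(frozen=True)
class ActivityLine:
    """Straight line relating inactive-state fraction to activity (%)."""

    a_wt: float = 100.0  # activity at p = 0
    a_bound: float = 0.0  # activity at p = 1

    def predict(self, p: float | np.ndarray) -> float | np.ndarray:
        return self.a_wt + np.asarray(p) * (self.a_bound - self.a_wt)


def activity_population_line(a_wt: float = 100.0, a_bound: float = 0.0) -> ActivityLine:
    """Line through the fully active (p=0) and fully inactive (p=1) states."""
    return ActivityLine(a_wt=a_wt, a_bound=a_bound)


def rmsd_about_line(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    line: ActivityLine | None = None,
) -> float:
    """R.m.s. deviation (activity %) of (p, activity) points from the line.

    ``points`` is a sequence of (population, activity_percent) pairs or a
    DataFrame with ``population`` and ``activity_percent`` columns.
    """
    line = line or ActivityLine()
    if isinstance(points, pd.DataFrame):
        p = points["population"].to_numpy(dtype=float)
        a = points["activity_percent"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.size == 0:
            raise ValueError("no variant points")
        p, a = arr[:, 0], arr[:, 1]
    if len(p) == 0:
        raise ValueError("no variant points")
    return float(np.sqrt(np.mean((a - line.predict(p)) ** 2)))
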