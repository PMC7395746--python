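"""Synthetic inputs for every stage of the analysis.

Generators emulate the statistical structure the analysis assumes, so each
stage can be exercised and validated end to end without any experimental
download:

* MQ-CPMG dispersion datasets at one or more static fields, with
  multiplicative Gaussian intensity noise (peak-height errors in
  methyl-TROSY spectra behave multiplicatively; default sigma 2%);
* titration peak lists in the fast-exchange regime (one population-averaged
  peak per site) or the slow-exchange regime (two peaks whose intensities
  split proportionally to the state populations);
* fluorescence deacetylation progress curves on the standard plate design
  (enzyme 0.2/0.4/0.6/0.8 uM, times 0-60 min step 10 min, substrate
  200 uM), strictly linear in time by default because the analysis uses
  only slopes -- an optional substrate-depletion mode exists for stress
  tests;
* ideal two-helix C-alpha coordinate sets (rise 1.5 A/residue, 100 degree
  twist/residue) with exactly constructed centre-of-mass separation and
  inter-axis angle, for validating the geometry observables.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .activity import PlateTimeCourse
from .csp import Peak, PeakList, classify_site
from .dispersion import DispersionDataset
from .exchange import CPMGSchedule, ExchangeParams, fast_exchange_shift, mq_r2eff_curve, snap_ncyc
from .geometry import StructureModel

__all__ = [
    "DEFAULT_FIELDS_MHZ",
    "DEFAULT_NU_CPMG",
    "SyntheticScenario",
    "TitrationScenario",
    "gen_dispersion_dataset",
    "gen_titration_peaklists",
    "gen_activity_plate",
    "gen_toy_helices",
]

#: 1H Larmor frequencies of the spectrometer park emulated by default (MHz)
DEFAULT_FIELDS_MHZ = (500.0, 600.0, 700.0, 800.0, 950.0)

#: requested CPMG frequencies, 20-1000 Hz: every realisable even pulse count
#: for Trelax = 30 ms, plus the 20 Hz request that snaps onto 66.7 Hz and so
#: doubles as the customary repeat point for error estimation
DEFAULT_NU_CPMG = (
    20.0, 66.7, 133.3, 200.0, 266.7, 333.3, 400.0, 466.7, 533.3,
    600.0, 666.7, 733.3, 800.0, 866.7, 933.3, 1000.0,
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth and acquisition design for dispersion simulation."""

    seed: int
    truth: ExchangeParams
    fields_mhz: tuple[float, ...] = (600.0, 800.0)
    trelax: float = 0.030
    nu_cpmg: tuple[float, ...] = DEFAULT_NU_CPMG
    intensity_noise: float = 0.02  # fraction of the peak intensity
    n_replicates: int = 1
    i0: float = 1.0e6

    def __post_init__(self) -> None:
        if self.intensity_noise < 0:
            raise ValueError("intensity noise must be non-negative")
        if any(f <= 0 for f in self.fields_mhz):
            raise ValueError("static fields must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def gen_dispersion_dataset(scenario: SyntheticScenario):
    """Simulate dispersion series for every site/field of the scenario.

    Intensities are I(nu) = I0 * exp(-R2eff_true(nu) * Trelax) * (1 + eps)
    with eps ~ Normal(0, intensity_noise); non-positive draws are rejected
    and redrawn (hard failure after 100 rejections per point).  The whole
    point table is replicated ``n_replicates`` times.  Per-point rate
    uncertainties are propagated from the intensity noise,
    sigma_R = intensity_noise / Trelax (a noise-free scenario gets a
    nominal 1e-6 floor so weights stay finite).

    Returns ``(datasets, raw)`` where ``raw`` is a tidy intensity table.
    """
    rng = np.random.default_rng(scenario.seed)
    sigma_r = max(scenario.intensity_noise, 1e-6) / scenario.trelax
    datasets, rows = [], []
    for site in sorted(scenario.truth.sites):
        for fmhz in scenario.fields_mhz:
            sched = CPMGSchedule(scenario.trelax, scenario.nu_cpmg, fmhz)
            r2_true = mq_r2eff_curve(scenario.truth, site, sched)
            nu_all, i_all, r2_all = [], [], []
            for _ in range(scenario.n_replicates):
                for j, nu in enumerate(scenario.nu_cpmg):
                    i_clean = scenario.i0 * np.exp(-r2_true[j] * scenario.trelax)
                    for attempt in range(100):
                        eps = rng.normal(0.0, scenario.intensity_noise) if scenario.intensity_noise else 0.0
                        i_obs = i_clean * (1.0 + eps)
                        if i_obs > 0:
                            break
                    else:
                        raise RuntimeError(
                            f"intensity at {site} {fmhz} MHz nu={nu} Hz stayed "
                            "non-positive after 100 redraws; noise level too large"
                        )
                    nu_all.append(nu)
                    i_all.append(i_obs)
                    r2_all.append(-np.log(i_obs / scenario.i0) / scenario.trelax)
                    rows.append(
                        {
                            "site": site,
                            "field_mhz": fmhz,
                            "trelax_s": scenario.trelax,
                            "nu_hz": nu,
                            "nu_realised_hz": snap_ncyc(nu, scenario.trelax) / scenario.trelax,
                            "intensity": i_obs,
                            "i0": scenario.i0,
                        }
                    )
            datasets.append(
                DispersionDataset(
                    site=site,
                    field_mhz=fmhz,
                    trelax=scenario.trelax,
                    nu=np.array(nu_all),
                    r2eff=np.array(r2_all),
                    sigma=np.full(len(nu_all), sigma_r),
                    i0=scenario.i0,
                    intensities=np.array(i_all),
                )
            )
    return datasets, pd.DataFrame(rows)


@dataclass(frozen=True)
class TitrationScenario:
    """Endpoint peak positions and populations for titration emulation.

    ``endpoints`` maps site -> (free (dH, dC), bound (dH, dC)) in ppm.
    In the fast regime each titration point yields one population-averaged
    peak per site; in the slow regime up to two peaks whose intensities are
    (1-p)*I0 and p*I0.
    """

    endpoints: Mapping[str, tuple[tuple[float, float], tuple[float, float]]]
    populations: tuple[float, ...]
    regime: str = "fast"
    peak_noise: float = 0.0  # ppm jitter (1H axis; 13C axis scaled by 5)
    seed: int = 0
    i0: float = 1.0e6

    def __post_init__(self) -> None:
        if self.regime not in ("fast", "slow"):
            raise ValueError(f"regime must be 'fast' or 'slow', got {self.regime!r}")
        if any(not 0.0 <= p <= 1.0 for p in self.populations):
            raise ValueError("populations must lie in [0, 1]")


def gen_titration_peaklists(scenario: TitrationScenario) -> list[PeakList]:
    """One peak list per titration point (per bound-state population)."""
    rng = np.random.default_rng(scenario.seed)
    out = []
    for p in scenario.populations:
        peaks = []
        for site, (free, bound) in scenario.endpoints.items():
            mclass = classify_site(site)
            if scenario.regime == "fast":
                dh, dc = fast_exchange_shift(p, free, bound)
                dh += rng.normal(0.0, scenario.peak_noise) if scenario.peak_noise else 0.0
                dc += rng.normal(0.0, 5.0 * scenario.peak_noise) if scenario.peak_noise else 0.0
                peaks.append(Peak(site, mclass, dh, dc, intensity=scenario.i0))
            else:
                # slow exchange: two resolved peaks, intensity split by population
                if p < 1.0:
                    peaks.append(Peak(site, mclass, free[0], free[1], intensity=(1 - p) * scenario.i0))
                if p > 0.0:
                    peaks.append(Peak(f"{site}b", mclass, bound[0], bound[1], intensity=p * scenario.i0))
        out.append(PeakList(peaks))
    return out


def gen_activity_plate(
    relative_efficiencies: Mapping[str, float],
    wt_kcat_over_km: float = 25.0,
    noise: float = 0.01,
    seed: int = 0,
    enzyme_uM: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    time_min: Sequence[float] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    substrate_uM: float = 200.0,
    f_background: float = 100.0,
    fluorescence_per_M: float = 1.0e8,
    depletion: bool = False,
) -> dict[str, PlateTimeCourse]:
    """Fluorescence progress curves per variant on the standard plate design.

    Each variant's efficiency is ``relative_efficiencies[variant] *
    wt_kcat_over_km`` (M^-1 s^-1).  In the default linear regime
    F(t) = F_bg + c*(kcat/KM)*[E]*[S]*t, multiplied pointwise by
    (1 + Normal(0, noise)); with ``depletion=True`` the exponential
    substrate-consumption curve is used instead (stress-test mode).
    """
    if any(v < 0 for v in relative_efficiencies.values()):
        raise ValueError("relative efficiencies must be non-negative")
    rng = np.random.default_rng(seed)
    e_molar = np.asarray(enzyme_uM, dtype=float) * 1e-6
    s_molar = substrate_uM * 1e-6
    t_s = np.asarray(time_min, dtype=float) * 60.0
    out = {}
    for variant, frac in relative_efficiencies.items():
        eff = frac * wt_kcat_over_km
        if depletion:
            product = s_molar * (1.0 - np.exp(-eff * e_molar[:, None] * t_s[None, :]))
        else:
            product = eff * e_molar[:, None] * s_molar * t_s[None, :]
        f = f_background + fluorescence_per_M * product
        if noise:
            f = f * (1.0 + rng.normal(0.0, noise, size=f.shape))
        out[variant] = PlateTimeCourse(
            variant=variant,
            enzyme_uM=np.asarray(enzyme_uM, dtype=float),
            time_min=np.asarray(time_min, dtype=float),
            fluorescence=f,
            substrate_uM=substrate_uM,
        )
    return out


def gen_toy_helices(
    separation: float,
    angle_deg: float,
    n_res_per_helix: int = 18,
    seed: int = 0,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
) -> StructureModel:
    """Two ideal C-alpha helices at an exact COM separation and axis angle.

    Helix A runs along +z with its centre of mass at the origin; helix B is
    rotated by ``angle_deg`` about the y axis and translated so its centre
    of mass sits at (separation, 0, 0).  Each helix is re-centred after
    construction, so the requested separation holds exactly for any residue
    count.  ``seed`` only randomises the helical phase of each helix.
    """
    if n_res_per_helix < 4:
        raise ValueError("need at least 4 residues per helix")
    rng = np.random.default_rng(seed)

    def ideal_helix(phase: float) -> np.ndarray:
        k = np.arange(n_res_per_helix)
        theta = np.radians(twist_deg) * k + phase
        xyz = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), rise * k]
        )
        return xyz - xyz.mean(axis=0)

    coords_a = ideal_helix(rng.uniform(0, 2 * np.pi))
    coords_b = ideal_helix(rng.uniform(0, 2 * np.pi))
    ang = np.radians(angle_deg)
    rot = np.array(
        [
            [np.cos(ang), 0.0, np.sin(ang)],
            [0.0, 1.0, 0.0],
            [-np.sin(ang), 0.0, np.cos(ang)],
        ]
    )
    coords_b = coords_b @ rot.T + np.array([separation, 0.0, 0.0])

    st = gemmi.Structure()
    st.name = "toy_helices"
    model = gemmi.Model("1")
    serial = 1
    for chain_name, coords, offset in (("A", coords_a, 0), ("B", coords_b, 100)):
        chain = gemmi.Chain(chain_name)
        for i, (x, y, z) in enumerate(coords, start=1):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(offset + i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 10.0
            atom.serial = serial
            serial += 1
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    return StructureModel(st)


def write_dispersion_csv(raw: pd.DataFrame, path: str | Path) -> None:
    """Tidy intensity table: site, field_mhz, trelax_s, nu_hz, intensity, i0."""
    raw.to_csv(path, index=False)


def write_plates_csv(plates: Mapping[str, PlateTimeCourse], path: str | Path) -> None:
    """Tidy plate table: variant, enzyme_uM, time_min, fluorescence."""
    pd.concat([tc.to_frame() for tc in plates.values()], ignore_index=True).to_csv(
        path, index=False
    )
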