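"""Global two-state fitting of MQ-CPMG relaxation dispersion data.

Workflow: raw peak intensities are converted to effective rates with
``r2eff_from_intensities``; per-site/per-field series are collected into
:class:`DispersionDataset` objects; :func:`global_fit` minimises

    chi^2 = sum_i [(R2eff_obs,i - R2eff_calc,i) / sigma_i]^2

over the global exchange parameters (kex, pm) shared by all included sites
and the local parameters (dwC per site, optionally dwH per selected site,
R2,0 per site per field).  Because two-state CPMG chi^2 surfaces are
multi-modal, the fit multi-starts from a grid of (kex, pm) values and
polishes the best start with a trust-region least-squares optimiser.

Whether a per-site dwH is warranted is decided by an F-test between nested
fits (``ftest_dwh``); parameter uncertainties come from the covariance
method, i.e. the diagonal of the inverse of the weighted-Jacobian normal
matrix at the optimum (``covariance_errors``).  ``validate_exchange_endpoint``
correlates the fitted |dwC| with independently measured chemical-shift
differences between the free and inhibitor-bound endpoint spectra.

Sign conventions: dwC is constrained non-negative (its sign is not
observable when dwH = 0); a fitted dwH may take either sign, which then
encodes the relative sign of the two shift differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .exchange import (
    GAMMA_RATIO_C_H,
    CPMGSchedule,
    ExchangeParams,
    SiteParams,
    _mq_amplitude,
    snap_ncyc,
)

__all__ = [
    "DispersionDataset",
    "FitConfig",
    "GlobalFitResult",
    "FTestResult",
    "EndpointValidation",
    "r2eff_from_intensities",
    "dataset_from_intensities",
    "datasets_from_frame",
    "datasets_to_frame",
    "global_fit",
    "ftest_dwh",
    "covariance_errors",
    "validate_exchange_endpoint",
]


@dataclass
class DispersionDataset:
    """One R2,eff-vs-nu series: a single site at a single static field."""

    site: str
    field_mhz: float
    trelax: float
    nu: np.ndarray  # Hz, as requested (replicates allowed)
    r2eff: np.ndarray  # s^-1
    sigma: np.ndarray  # s^-1
    i0: float | None = None
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.nu) == len(self.r2eff) == len(self.sigma)):
            raise ValueError("nu, r2eff and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("every point needs a positive uncertainty")

    @property
    def schedule(self) -> CPMGSchedule:
        return CPMGSchedule(self.trelax, tuple(self.nu), self.field_mhz)


def r2eff_from_intensities(
    i_nu: Sequence[float],
    i0: float,
    trelax: float,
    nu: Sequence[float] | None = None,
    sigma_i: float | Sequence[float] | None = None,
    noise_floor: float = 0.01,
):
    """Convert peak intensities to effective rates.

    R2,eff(nu) = -ln(I_nu / I0) / Trelax, with the rate uncertainty
    propagated as sigma_R = sigma_I / (I_nu * Trelax).  The intensity
    uncertainty is, in order of preference: the supplied ``sigma_i``; the
    pooled standard deviation of replicate ``nu`` points; the
    ``noise_floor`` fraction of I0.

    Returns ``(r2eff, sigma, valid)``; non-positive intensities are flagged
    invalid (NaN rate) rather than silently clamped.
    """
    if not i0 > 0:
        raise ValueError("reference intensity I0 must be positive")
    if not trelax > 0:
        raise ValueError("Trelax must be positive")
    i_nu = np.asarray(i_nu, dtype=float)
    valid = i_nu > 0

    r2eff = np.full(i_nu.shape, np.nan)
    r2eff[valid] = -np.log(i_nu[valid] / i0) / trelax

    if sigma_i is None:
        pooled = _replicate_sigma(i_nu, nu) if nu is not None else None
        sigma_i = pooled if pooled is not None else noise_floor * i0
        sigma_i = max(float(sigma_i), noise_floor * i0)
    sigma_i = np.broadcast_to(np.asarray(sigma_i, dtype=float), i_nu.shape)
    sigma = np.full(i_nu.shape, np.nan)
    sigma[valid] = sigma_i[valid] / (i_nu[valid] * trelax)
    return r2eff, sigma, valid


def _replicate_sigma(i_nu: np.ndarray, nu: Sequence[float]) -> float | None:
    """Pooled SD of intensities over repeated nu values, if any."""
    nu = np.asarray(nu, dtype=float)
    ss, dof = 0.0, 0
    for v in np.unique(nu):
        grp = i_nu[np.isclose(nu, v)]
        if len(grp) > 1:
            ss += np.sum((grp - grp.mean()) ** 2)
            dof += len(grp) - 1
    if dof == 0:
        return None
    return float(np.sqrt(ss / dof))


def dataset_from_intensities(
    site: str,
    field_mhz: float,
    trelax: float,
    nu: Sequence[float],
    i_nu: Sequence[float],
    i0: float,
    sigma_i: float | None = None,
    noise_floor: float = 0.01,
) -> DispersionDataset:
    """Build a dataset from raw intensities, dropping invalid points."""
    r2eff, sigma, valid = r2eff_from_intensities(
        i_nu, i0, trelax, nu=nu, sigma_i=sigma_i, noise_floor=noise_floor
    )
    nu = np.asarray(nu, dtype=float)
    return DispersionDataset(
        site=site,
        field_mhz=field_mhz,
        trelax=trelax,
        nu=nu[valid],
        r2eff=r2eff[valid],
        sigma=sigma[valid],
        i0=i0,
        intensities=np.asarray(i_nu, dtype=float)[valid],
    )


def datasets_from_frame(frame: pd.DataFrame, noise_floor: float = 0.01):
    """Read series from a tidy table.

    Expected columns: ``site, field_mhz, nu_hz, trelax_s`` plus either
    ``r2eff, sigma`` or ``intensity, i0``.
    """
    out = []
    for (site, fmhz), grp in frame.groupby(["site", "field_mhz"], sort=True):
        trelax = float(grp["trelax_s"].iloc[0])
        if "r2eff" in grp.columns and grp["r2eff"].notna().all():
            out.append(
                DispersionDataset(
                    site=str(site),
                    field_mhz=float(fmhz),
                    trelax=trelax,
                    nu=grp["nu_hz"].to_numpy(),
                    r2eff=grp["r2eff"].to_numpy(),
                    sigma=grp["sigma"].to_numpy(),
                )
            )
        else:
            out.append(
                dataset_from_intensities(
                    str(site),
                    float(fmhz),
                    trelax,
                    grp["nu_hz"].to_numpy(),
                    grp["intensity"].to_numpy(),
                    float(grp["i0"].iloc[0]),
                    noise_floor=noise_floor,
                )
            )
    return out


def datasets_to_frame(datasets: Iterable[DispersionDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for j in range(len(ds.nu)):
            rows.append(
                {
                    "site": ds.site,
                    "field_mhz": ds.field_mhz,
                    "trelax_s": ds.trelax,
                    "nu_hz": ds.nu[j],
                    "r2eff": ds.r2eff[j],
                    "sigma": ds.sigma[j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Options controlling the global dispersion fit.

    ``exclude_sites`` removes series from the shared-(kex, pm) fit entirely
    (sites whose dispersion stems from a different process are data to
    exclude, not code).  ``fit_dwh`` lists the sites for which a proton
    shift difference is a free parameter; all other sites keep dwH = 0.
    """

    kex_grid: tuple[float, ...] = (200.0, 500.0, 1000.0, 2000.0, 4000.0)
    pm_grid: tuple[float, ...] = (0.01, 0.05, 0.15)
    fit_dwh: frozenset[str] = frozenset()
    exclude_sites: frozenset[str] = frozenset()
    kex_bounds: tuple[float, float] = (1.0, 30000.0)
    pm_bounds: tuple[float, float] = (1e-4, 0.4999)
    dwc_bounds: tuple[float, float] = (0.0, 6.0)
    dwh_bounds: tuple[float, float] = (-2.0, 2.0)
    probe_nfev: int = 40  # budget per multi-start probe
    polish_starts: int = 2  # best probes polished to convergence


@dataclass
class GlobalFitResult:
    """Best-fit parameters, uncertainties and fit diagnostics."""

    kex: float
    kex_sigma: float
    pm: float
    pm_sigma: float
    dwc: dict[str, float]
    dwc_sigma: dict[str, float]
    dwh: dict[str, float]
    dwh_sigma: dict[str, float]
    r20: dict[tuple[str, float], float]
    r20_sigma: dict[tuple[str, float], float]
    chi2: float
    nobs: int
    nparams: int
    cov: np.ndarray
    param_names: list[str]
    identifiable: bool
    unidentifiable_params: list[str]
    datasets: list[DispersionDataset] = field(repr=False, default_factory=list)

    @property
    def redchi(self) -> float:
        return self.chi2 / max(self.nobs - self.nparams, 1)

    @property
    def phi(self) -> dict[str, float]:
        """pm(1-pm)*dwC^2 per site (ppm^2), the fast-exchange observable."""
        q = self.pm * (1.0 - self.pm)
        return {s: q * d**2 for s, d in self.dwc.items()}

    @property
    def sqrt_phi(self) -> dict[str, float]:
        """sqrt(pm(1-pm))*|dwC| per site (ppm)."""
        q = np.sqrt(self.pm * (1.0 - self.pm))
        return {s: q * abs(d) for s, d in self.dwc.items()}

    def exchange_params(self) -> ExchangeParams:
        sites = {}
        for s in self.dwc:
            r20 = {
                f: v for (site, f), v in self.r20.items() if site == s
            }
            sites[s] = SiteParams(self.dwc[s], self.dwh.get(s, 0.0), r20)
        return ExchangeParams(self.kex, min(self.pm, 0.49989), sites)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": "kex", "site": "", "value": self.kex, "sigma": self.kex_sigma},
            {"parameter": "pm", "site": "", "value": self.pm, "sigma": self.pm_sigma},
        ]
        for s in sorted(self.dwc):
            rows.append({"parameter": "dwC_ppm", "site": s, "value": self.dwc[s], "sigma": self.dwc_sigma[s]})
            rows.append({"parameter": "dwH_ppm", "site": s, "value": self.dwh.get(s, 0.0), "sigma": self.dwh_sigma.get(s, 0.0)})
            rows.append({"parameter": "phi_ppm2", "site": s, "value": self.phi[s], "sigma": np.nan})
        for (s, f), v in sorted(self.r20.items()):
            rows.append({"parameter": f"R20_{f:g}MHz", "site": s, "value": v, "sigma": self.r20_sigma[(s, f)]})
        return pd.DataFrame(rows)


class _ParamLayout:
    """Maps the flat optimiser vector onto named model parameters."""

    def __init__(self, datasets, config: FitConfig):
        self.sites = sorted({ds.site for ds in datasets})
        self.series = [(ds.site, ds.field_mhz) for ds in datasets]
        self.dwh_sites = sorted(set(config.fit_dwh) & set(self.sites))
        self.names = ["kex", "pm"]
        self.names += [f"dwC[{s}]" for s in self.sites]
        self.names += [f"dwH[{s}]" for s in self.dwh_sites]
        self.names += [f"R20[{s}@{f:g}]" for s, f in self.series]
        self.n = len(self.names)

    def unpack(self, x):
        ns = len(self.sites)
        nh = len(self.dwh_sites)
        kex, pm = x[0], x[1]
        dwc = dict(zip(self.sites, x[2 : 2 + ns]))
        dwh = dict(zip(self.dwh_sites, x[2 + ns : 2 + ns + nh]))
        r20 = dict(zip(self.series, x[2 + ns + nh :]))
        return kex, pm, dwc, dwh, r20

    def bounds(self, config: FitConfig):
        lo = [config.kex_bounds[0], config.pm_bounds[0]]
        hi = [config.kex_bounds[1], config.pm_bounds[1]]
        lo += [config.dwc_bounds[0]] * len(self.sites)
        hi += [config.dwc_bounds[1]] * len(self.sites)
        lo += [config.dwh_bounds[0]] * len(self.dwh_sites)
        hi += [config.dwh_bounds[1]] * len(self.dwh_sites)
        lo += [0.0] * len(self.series)
        hi += [500.0] * len(self.series)
        return np.array(lo), np.array(hi)


class _Design:
    """Flattened point-level arrays for fast residual evaluation."""

    def __init__(self, datasets, layout: _ParamLayout):
        ns, nh = len(layout.sites), len(layout.dwh_sites)
        site_pos = {s: i for i, s in enumerate(layout.sites)}
        dwh_pos = {s: i for i, s in enumerate(layout.dwh_sites)}
        series_pos = {key: i for i, key in enumerate(layout.series)}
        dwc_idx, dwh_idx, r20_idx = [], [], []
        ncyc, trelax, scale_c, scale_h, obs, sigma = [], [], [], [], [], []
        for ds in datasets:
            for j in range(len(ds.nu)):
                dwc_idx.append(2 + site_pos[ds.site])
                dwh_idx.append(
                    2 + ns + dwh_pos[ds.site] if ds.site in dwh_pos else -1
                )
                r20_idx.append(2 + ns + nh + series_pos[(ds.site, ds.field_mhz)])
                ncyc.append(snap_ncyc(ds.nu[j], ds.trelax))
                trelax.append(ds.trelax)
                scale_c.append(2 * np.pi * ds.field_mhz * GAMMA_RATIO_C_H)
                scale_h.append(2 * np.pi * ds.field_mhz)
                obs.append(ds.r2eff[j])
                sigma.append(ds.sigma[j])
        self.dwc_idx = np.array(dwc_idx)
        self.dwh_idx = np.array(dwh_idx)
        self.has_dwh = self.dwh_idx >= 0
        self.r20_idx = np.array(r20_idx)
        self.ncyc = np.array(ncyc)
        self.trelax = np.array(trelax)
        self.scale_c = np.array(scale_c)
        self.scale_h = np.array(scale_h)
        self.obs = np.array(obs)
        self.sigma = np.array(sigma)

    def model(self, x: np.ndarray) -> np.ndarray:
        dwh_ppm = np.where(self.has_dwh, x[self.dwh_idx], 0.0)
        amp = _mq_amplitude(
            x[0],
            x[1],
            self.scale_c * x[self.dwc_idx],
            self.scale_h * dwh_ppm,
            x[self.r20_idx],
            self.trelax,
            self.ncyc,
        )
        return -np.log(np.maximum(amp, 1e-300)) / self.trelax

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return (self.model(x) - self.obs) / self.sigma


def _initial_locals(datasets, kex0, pm0):
    """Data-driven starting values for the local parameters."""
    r20_init, rex_by_site = {}, {}
    for ds in datasets:
        order = np.argsort(ds.nu)
        hi = ds.r2eff[order][-2:].mean()
        lo = ds.r2eff[order][:2].mean()
        r20_init[(ds.site, ds.field_mhz)] = max(hi, 0.1)
        rex_by_site.setdefault(ds.site, []).append((max(lo - hi, 0.0), ds.field_mhz))
    dwc_init = {}
    for site, entries in rex_by_site.items():
        # fast-exchange guess: Rex ~ pm(1-pm) dw^2 / kex
        vals = []
        for rex, fmhz in entries:
            dw_rad = np.sqrt(max(rex, 1e-3) * kex0 / (pm0 * (1 - pm0)))
            vals.append(dw_rad / (2 * np.pi * fmhz * 0.25143))
        dwc_init[site] = float(np.clip(np.mean(vals), 0.05, 4.0))
    return r20_init, dwc_init


def global_fit(
    datasets: Sequence[DispersionDataset],
    config: FitConfig | None = None,
) -> GlobalFitResult:
    """Globally fit the two-state model across sites and fields.

    All non-excluded series share (kex, pm); each site contributes its own
    dwC (and dwH when selected by ``config.fit_dwh``) and each series its own
    R2,0.  Raises ``ValueError`` when no series remain.
    """
    config = config or FitConfig()
    datasets = [ds for ds in datasets if ds.site not in config.exclude_sites]
    if not datasets:
        raise ValueError("no dispersion series to fit")
    layout = _ParamLayout(datasets, config)
    lo, hi = layout.bounds(config)

    # identifiability screen: is there any dispersion above the noise?
    rex_snr = []
    for ds in datasets:
        order = np.argsort(ds.nu)
        rex = ds.r2eff[order][:2].mean() - ds.r2eff[order][-2:].mean()
        rex_snr.append(rex / np.median(ds.sigma))
    identifiable = bool(np.max(rex_snr) > 3.0)

    def make_x0(kex0, pm0):
        r20_init, dwc_init = _initial_locals(datasets, kex0, pm0)
        x0 = [kex0, pm0]
        x0 += [dwc_init[s] for s in layout.sites]
        x0 += [0.0] * len(layout.dwh_sites)
        x0 += [r20_init[key] for key in layout.series]
        return np.clip(np.array(x0), lo + 1e-12, hi - 1e-12)

    design = _Design(datasets, layout)
    probes = []
    for kex0, pm0 in itertools.product(config.kex_grid, config.pm_grid):
        sol = least_squares(
            design.residuals,
            make_x0(kex0, pm0),
            bounds=(lo, hi),
            method="trf",
            max_nfev=config.probe_nfev,
        )
        probes.append(sol)
    probes.sort(key=lambda s: s.cost)

    best = None
    for sol in probes[: config.polish_starts]:
        polished = least_squares(
            design.residuals,
            sol.x,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=2000,
        )
        if best is None or polished.cost < best.cost:
            best = polished

    chi2 = float(2.0 * best.cost)
    cov, bad = _covariance_from_jacobian(best.jac, layout.names)
    kex, pm, dwc, dwh, r20 = layout.unpack(best.x)
    sig = {name: float(np.sqrt(cov[i, i])) for i, name in enumerate(layout.names)}

    return GlobalFitResult(
        kex=float(kex),
        kex_sigma=sig["kex"],
        pm=float(pm),
        pm_sigma=sig["pm"],
        dwc={s: float(v) for s, v in dwc.items()},
        dwc_sigma={s: sig[f"dwC[{s}]"] for s in dwc},
        dwh={s: float(dwh.get(s, 0.0)) for s in layout.sites},
        dwh_sigma={
            s: sig[f"dwH[{s}]"] if s in layout.dwh_sites else 0.0
            for s in layout.sites
        },
        r20={k: float(v) for k, v in r20.items()},
        r20_sigma={(s, f): sig[f"R20[{s}@{f:g}]"] for s, f in layout.series},
        chi2=chi2,
        nobs=sum(len(ds.nu) for ds in datasets),
        nparams=layout.n,
        cov=cov,
        param_names=list(layout.names),
        identifiable=identifiable,
        unidentifiable_params=bad,
        datasets=list(datasets),
    )


def _covariance_from_jacobian(jac: np.ndarray, names: Sequence[str]):
    """Covariance method: inverse of the normal matrix J^T J.

    Residuals are already sigma-weighted, so no reduced-chi^2 scaling is
    applied.  Near-singular directions are inverted by pseudo-inverse and the
    corresponding parameters reported as unidentifiable.
    """
    jtj = jac.T @ jac
    u, s, vt = np.linalg.svd(jtj)
    tol = s.max() * len(names) * np.finfo(float).eps if s.size else 0.0
    bad_dirs = s < max(tol, 1e-300)
    s_inv = np.where(bad_dirs, 0.0, 1.0 / np.where(bad_dirs, 1.0, s))
    cov = vt.T @ np.diag(s_inv) @ u.T
    bad = []
    if np.any(bad_dirs):
        weight = np.abs(vt[bad_dirs]).sum(axis=0)
        bad = [n for n, w in zip(names, weight) if w > 0.5]
        for i, n in enumerate(names):
            if n in bad:
                cov[i, i] = np.inf
    return cov, bad


def covariance_errors(result: GlobalFitResult) -> dict[str, float]:
    """Per-parameter standard errors from the fitted covariance matrix.

    Parameters flagged unidentifiable carry an infinite error.
    """
    return {
        name: float(np.sqrt(result.cov[i, i]))
        for i, name in enumerate(result.param_names)
    }


# ---------------------------------------------------------------------------
# Model selection and validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FTestResult:
    site: str
    f_statistic: float
    p_value: float
    include_dwh: bool
    dwh: float
    dwh_sigma: float


def ftest_dwh(
    fit_without: GlobalFitResult,
    fit_with: GlobalFitResult,
    site: str,
    alpha: float = 0.05,
) -> FTestResult:
    """F-test for whether a free dwH at ``site`` improves the fit.

    F = ((chi2_reduced - chi2_full)/dp) / (chi2_full/(N - p_full)) with dp
    the number of added parameters; dwH is included iff p < ``alpha``.
    Fits must be nested (identical data, the richer model adding dwH).
    """
    if fit_without.nobs != fit_with.nobs:
        raise ValueError("fits are not nested: different numbers of observations")
    dp = fit_with.nparams - fit_without.nparams
    if dp <= 0:
        raise ValueError("fits are not nested: the full model adds no parameter")
    dof = fit_with.nobs - fit_with.nparams
    if dof <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    f_stat = ((fit_without.chi2 - fit_with.chi2) / dp) / (fit_with.chi2 / dof)
    f_stat = max(f_stat, 0.0)
    p_value = float(stats.f.sf(f_stat, dp, dof))
    include = p_value < alpha
    return FTestResult(
        site=site,
        f_statistic=float(f_stat),
        p_value=p_value,
        include_dwh=include,
        dwh=fit_with.dwh.get(site, 0.0) if include else 0.0,
        dwh_sigma=fit_with.dwh_sigma.get(site, 0.0) if include else 0.0,
    )


@dataclass
class EndpointValidation:
    pearson_r: float
    p_value: float
    table: pd.DataFrame
    pearson_r_sqrtphi: float | None = None


def validate_exchange_endpoint(
    fit: GlobalFitResult,
    shifts_free,
    shifts_bound,
    min_sites: int = 3,
) -> EndpointValidation:
    """Correlate fitted |dwC| with free-to-bound 13C shift differences.

    ``shifts_free``/``shifts_bound`` are peak lists (site -> peak with
    ``dc`` in ppm).  Also reports the correlation of the robustly
    identifiable combination sqrt(pm(1-pm))*|dwC| with the same shift
    differences.  Fewer than ``min_sites`` shared sites leaves r undefined.
    """
    shared = sorted(set(fit.dwc) & set(shifts_free.sites()) & set(shifts_bound.sites()))
    rows = []
    for s in shared:
        ddc = abs(shifts_bound[s].dc - shifts_free[s].dc)
        rows.append(
            {
                "site": s,
                "abs_dwc_cpmg_ppm": abs(fit.dwc[s]),
                "abs_ddc_endpoint_ppm": ddc,
                "sqrt_phi_ppm": fit.sqrt_phi[s],
            }
        )
    table = pd.DataFrame(rows)
    if len(shared) < min_sites:
        return EndpointValidation(float("nan"), float("nan"), table, None)
    r, p = stats.pearsonr(table["abs_dwc_cpmg_ppm"], table["abs_ddc_endpoint_ppm"])
    r2, _ = stats.pearsonr(table["sqrt_phi_ppm"], table["abs_ddc_endpoint_ppm"])
    return EndpointValidation(float(r), float(p), table, float(r2))
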