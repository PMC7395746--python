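# Methods

## Two-state multiple-quantum CPMG model

The forward model describes a methyl group exchanging between a major state
A (population 1−p_m) and a minor state B (population p_m) with overall rate
k_ex = k_forward + k_backward, k_forward = p_m·k_ex. During the constant-time
CPMG element the ¹H–¹³C multiple-quantum coherence is tracked as a
4-dimensional complex vector (DQ_A, DQ_B, ZQ_A, ZQ_B). The major state
defines the rotating-frame reference; in the minor state the DQ component
precesses at Δω_H + Δω_C and the ZQ component at Δω_H − Δω_C (rad/s, with
Δω_C[rad/s] = 2π·B₀[MHz]·0.25143·Δω_C[ppm] and the analogous factor 1 for
¹H). Free-precession blocks are closed-form 2×2 matrix exponentials of the
evolution-plus-exchange generator; a ¹³C π pulse swaps DQ↔ZQ; the single
¹H π at T/2 swaps DQ↔ZQ and conjugates the vector. Pulses are ideal and
instantaneous. The propagator starts from the equilibrium population vector
and the detected signal is the major-state component normalised by its
initial amplitude, so that R₂,eff(ν→∞) → R₂,₀ exactly when Δω_H = 0.

Pulse-count convention: ν_CPMG = n/T_relax with n the number of ¹³C π
pulses arranged as n repetitions of (τ−π−τ). The midpoint ¹H π must fall in
a delay, so n is snapped to the nearest even integer (minimum 2) and the
realised frequency is recorded next to the requested one. With T_relax =
30 ms the lowest requested frequency of the standard 20–1000 Hz series
(20 Hz) is not realisable and snaps onto 66.7 Hz, where it serves as the
customary duplicate point.

R₂,₀ is one value per site per field, identical for DQ and ZQ coherences
and for both states; differential DQ/ZQ relaxation is out of scope. The
exact basis-set composition used by established dispersion-analysis
software is not uniquely documented; this 4-dimensional DQ/ZQ construction
is validated against an independent dense integrator (RK4 on the full
Bloch–McConnell equations, step ≤ 1 µs, identical pulse placements), with
agreement far below 0.01 s⁻¹ over the full parameter range exercised, and
reduces exactly to the single-quantum two-state propagator when Δω_H = 0.

## Global fitting

χ² = Σ[(R₂,eff,obs − R₂,eff,calc)/σ]² is minimised over global (k_ex, p_m)
and local (Δω_C ≥ 0, optional Δω_H ∈ [−2, 2] ppm, R₂,₀) parameters with
scipy's trust-region-reflective least squares. Because the χ² surface is
multi-modal, the fit multi-starts from the grid k_ex ∈ {200, 500, 1000,
2000, 4000} s⁻¹ × p_m ∈ {0.01, 0.05, 0.15}, with data-driven starting
values for the local parameters (R₂,₀ from the high-ν plateau, Δω_C from
the fast-exchange Rex relation); each probe runs a capped number of
iterations and the best ones are polished to convergence. Simulation
studies that fit many replicates of a well-conditioned design may pass a
reduced grid through `FitConfig`; the default grid is always used when
nothing is specified.

Relabelling the two states (p_m → 1−p_m with the observable moved to the
other state) leaves every R₂,eff unchanged, so the fitter resolves the
ambiguity by bounding p_m < 0.5. The sign of Δω_C is unobservable when
Δω_H = 0 and is fixed non-negative; a fitted Δω_H may take either sign,
which encodes the relative sign of the two shift differences.

Uncertainties use the covariance method: the inverse of J^T J at the
optimum with σ-weighted residuals (no reduced-χ² rescaling, since the point
uncertainties are taken at face value); doubling all data σ therefore
doubles every parameter σ. Singular directions are inverted by
pseudo-inverse and the parameters dominating them are flagged
unidentifiable. A dataset whose largest low-ν/high-ν rate difference is
below three times the median σ raises a global identifiability flag.

Per-site Δω_H inclusion is decided by the F-test
F = ((χ²_reduced − χ²_full)/Δp)/(χ²_full/(N − p_full)) at the 95 % level,
performed inside the global fit so that the companion sites pin (k_ex,
p_m); sites not selected keep Δω_H = 0. Under the synthetic study
conditions (one 0.10 ppm site, Δω_C = 0.5 ppm, two fields, 2 % intensity
noise) the test's noncentrality is ≈ 4, i.e. its power at the 95 % level is
around 50–80 % depending on the companion set — repeats in which the site
is not selected are expected, and the reported shift difference is the
median over the selected repeats.

φ = p_m(1−p_m)Δω_C² (ppm²) and √(p_m(1−p_m))·|Δω_C| (ppm) are reported per
site: in the fast-exchange regime p_m and Δω_C are individually degenerate
(only their product is pinned by the data) while φ remains identifiable up
to the k_ex determination. The corresponding property test compares
relative errors on the commensurate squared-shift scale.

## Exchange-regime diagnostic

α = ln(Rex(B_high)/Rex(B_low)) / ln(B_high/B_low), with Rex :=
R₂,eff(ν_min) − R₂,eff(ν_max) on the schedule in use. α → 2 in fast
exchange and → 0 in slow exchange; values above ~1.2 indicate that only φ
is recoverable. Note that with a finite ν window the slow-exchange limit is
only reached when ν_max is large enough to refocus Δω; limit tests use a
widened schedule for exactly this reason.

## Chemical-shift perturbations

ΔCS combines per-axis displacements scaled by the BMRB-derived standard
deviations of assigned methyl shifts: (0.28, 1.66) ppm for Ile-δ1 and
(0.38, 1.67) ppm for Met-ε. Constants for Leu/Val are deliberately not
built in (none are established for this workflow) and must be supplied
explicitly. No significance threshold exists for calling a site
"affected"; the report ranks sites by ΔCS and flags those above
mean + 1 SD, with both the flag and the cutoff exposed. Matching is by
assignment label only.

## Population projection

Peak positions are first expressed in scaled coordinates (δ_H/c_H, δ_C/c_C
with the ΔCS constants) so the two axes are commensurate — the choice is
config-overridable (`scaling="raw"`) and recorded in the output, since raw
ppm would weight ¹³C displacements ~6× more. Per reporter site,
p_i = (x_var−x_free)·(x_bound−x_free)/|x_bound−x_free|², with the
orthogonal residual quantifying deviations from the two-endpoint picture.
Reporters combine by unweighted mean (median and axis-length-weighted
variants available); projections are not clipped to [0, 1] — out-of-range
values flag pathology instead of hiding it. No correction is applied for
through-space effects of mutations on the reporter shifts.

Activity is predicted as â(p) = a_wt + p(a_bound − a_wt) with a_wt = 100 %
at p = 0 and a_bound = 0 % at p = 1; cohort scatter is reported as
r.m.s.d. = √(mean (a_i − â(p_i))²).

## Activity assays

The assay design is four enzyme concentrations (0.2/0.4/0.6/0.8 µM), seven
time points (0–60 min, step 10) and one substrate concentration (200 µM,
far below saturation), so v₀ = OLS slope of fluorescence vs time and
k_cat/K_M ∝ slope of v₀ vs [E] (intercept free and reported). All
activities are ratios, so no fluorescence calibration is needed. The
r.m.s.d. error of a relative activity re-runs the full pipeline on
jackknifed sub-assays — leaving out one enzyme concentration at a time and
one time point at a time, in both variants simultaneously — and takes the
root-mean-square deviation of the sub-assay ratios about the full-data
value. Blank subtraction is available (`blank=`) but off by default; a
constant offset does not change slopes.

## Helix geometry

Alternate conformations are resolved before any measurement (highest
occupancy, ties to altloc 'A'). Centre-of-mass distances are mass-weighted
over heavy atoms. Helix axes are the first principal component of the Cα
coordinates, oriented N→C; for selections of ≥ 6 residues the coordinates
are first smoothed with a 4-residue moving average, which collapses the
helical wheel and removes the ~2° tilt raw PCA picks up when a selection
spans a non-integer number of turns. Helix residue ranges are configuration
data, defaulting to the file's HELIX records. Distances "to the active
site" use the catalytic zinc (nearest ZN HETATM) as the conventional
marker. Ensembles are multi-model PDB; distribution summaries are the
plain per-model summaries, with no weighting.

## Synthetic data: what it does and does not emulate

Dispersion: I(ν) = I₀·exp(−R₂,eff·T_relax)·(1+ε), ε ~ N(0, σ) with σ = 2 %
of the peak intensity by default (multiplicative noise matches how
peak-height errors behave); non-positive draws are rejected and redrawn,
with a hard failure after 100 rejections. The propagated per-point rate
uncertainty is σ/T_relax. The default acquisition is every realisable even
pulse count for T_relax = 30 ms (66.7–1000 Hz) plus the snapped 20 Hz
duplicate, at any subset of the {500, 600, 700, 800, 950} MHz spectrometer
park (simulation studies default to 600 + 800 MHz). The reference
intensity I₀ is noise-free. Not emulated: lineshapes, peak overlap,
temperature or pulse miscalibration, differential DQ/ZQ relaxation — so
passing tests validate the fitting machinery under the stated noise model,
not robustness to spectral artefacts.

Titration: fast regime emits one population-averaged peak per site; slow
regime emits two peaks at the endpoint positions with intensities
(1−p)·I₀ and p·I₀. Intermediate-exchange broadening is not modelled.

Plates: strictly linear progress curves F(t) = F_bg + c·(k_cat/K_M)[E][S]t
by default, since the analysis uses only slopes; the wild-type efficiency
default (25 M⁻¹s⁻¹) keeps product formation below 10 % of substrate over
the hour so the linear regime is self-consistent. A depletion flag switches
to the exponential substrate-consumption curve for stress tests.

Helices: ideal Cα-only geometry (rise 1.5 Å/residue, 100°/residue, radius
2.3 Å, default 18 residues = 5 exact turns), re-centred after construction
so the requested centre-of-mass separation holds exactly for any residue
count. The seed only randomises helical phases.

## Problem sizes used in validation

Simulation studies run at 6 sites × 2 fields × 16 CPMG frequencies for
exchange-rate recovery (20 repeats), 3 sites for the Δω_H F-test power
study and 2 sites × 100 repeats for its type-I error calibration, and
20-repeat plate studies for activity recovery. These sizes were chosen to
represent one methyl class of a well-behaved sample on two spectrometers.
Under these conditions the maximum-likelihood spread of the recovered
free-enzyme k_ex is ≈ 215 s⁻¹ (the Cramér–Rao limit of the design — the
fitter reproduces noise-free data exactly and matches its own covariance
estimate), which is wider than the uncertainty a full many-site,
many-field dataset supports; recovery-rate checks against the narrower
published band therefore fail at this scale while the median recovered
rate agrees closely.

## Known limitations

- Two-state exchange only; no three-state or ligand-binding kinetic models.
- No spectral processing or lineshape analysis — inputs are peak/intensity
  tables.
- The MQ basis omits differential DQ/ZQ intrinsic relaxation.
- Δω_H selection power at realistic noise is modest (see above); the F-test
  calibration, not the power, is the guaranteed property.
- Population projection assumes the fast-exchange limit for every variant
  peak and exactly two endpoint states.
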