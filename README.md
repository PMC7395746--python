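# methylex

Quantifying sparsely populated protein conformational states from
methyl-TROSY NMR, with HDAC8-style allosteric regulation as the model
problem: an enzyme that interconverts on the µs–ms time-scale between an
active major state and a lowly populated inactive state, so that anything
shifting that equilibrium (inhibitor binding, point mutations,
phosphomimetics) tunes activity without touching the catalytic machinery.

The package is aimed at NMR spectroscopists and structural biologists who
have peak lists, CPMG intensity tables, plate-reader progress curves and
coordinate files, and want one consistent toolchain from raw tables to
populations, exchange parameters and geometry.

## What it computes

**Two-state MQ-CPMG relaxation dispersion.** Methyl ¹H–¹³C multiple-quantum
coherence is propagated through the constant-time CPMG element as a
4-dimensional complex vector (DQ and ZQ components in both exchanging
states): free precession blocks are matrix exponentials of the
Bloch–McConnell generator, ¹³C π pulses swap DQ↔ZQ, and the single ¹H π at
T/2 conjugates the proton part. The observable is

    R₂,eff(ν) = −ln(Iν / I₀) / T_relax

and the model is fitted globally across sites and static fields by weighted
trust-region least squares with multi-start over a (k_ex, p_m) grid:
global k_ex = k_forward + k_backward and minor-state population p_m, plus
per-site Δω_C (and Δω_H where a 95 % F-test warrants it) and per-site,
per-field intrinsic rates R₂,₀. Uncertainties come from the covariance
method; the fast-exchange observable φ = p_m(1−p_m)Δω² and the exchange-regime
exponent α = ∂ln R_ex/∂ln B₀ are reported alongside.

**Chemical-shift perturbations.** ΔCS = √((Δδ_H/0.28)² + (Δδ_C/1.66)²) for
Ile-δ1 (0.38/1.67 for Met-ε), with disappeared/new-peak flags and
structure-viewer attribute output.

**Populations from fast exchange.** When a variant exchanges rapidly between
the active and an inhibitor-bound-like state, each reporter peak sits at the
population-weighted average position; the inactive fraction is the scalar
projection of the variant peak onto the free→bound vector in scaled shift
coordinates, combined over reporters (default I45, I56, I284) and related to
relative enzymatic activity through the line connecting the fully active and
fully inactive endpoints.

**Activity assays.** Initial rates v₀ from fluorescence-vs-time slopes,
catalytic efficiency ∝ k_cat/K_M from the slope of v₀ vs [E], relative
activity as a percentage of wild type with a jackknife r.m.s.d. error.

**Helix geometry.** Centre-of-mass distances, PCA-based inter-helix angles
and named atom–atom distances (e.g. K33 Cα–F152 Cα, or any atom to the
catalytic zinc) on single structures or multi-model PDB ensembles.

A synthetic-data module generates statistically faithful inputs for every
stage — dispersion datasets with multiplicative intensity noise, titration
peak lists in fast- and slow-exchange regimes, plate progress curves and
ideal two-helix coordinate sets — so the whole pipeline is testable without
downloading anything.

## Worked example

```sh
methylex replay --seed 3 --out rep
```

prints (abridged):

```
Two-state exchange fit on synthetic dispersion data
  truth    kex = 1950 1/s, pm = 0.030
  fitted   kex = 2207 +/- 289 1/s, pm = 0.0348 +/- 0.0055
  reduced chi2 = 0.94; endpoint-shift correlation r = 0.999

Variant populations and activities
  S39E     p(inactive) = 0.770 activity = 22.9% +/- 0.2%
  M40A     p(inactive) = 0.730 activity = 26.6% +/- 0.2%
  F336A    p(inactive) = 0.460 activity = 53.6% +/- 0.4%
  r.m.s.d. about the activity-population line: 0.3%

Helix geometry on the constructed two-helix model
  COM distance = 12.00 A (requested 12.0)
  inter-helix angle = 24.8 deg (requested 25.0)
```

Six sites of two-field dispersion data were simulated at k_ex = 1950 s⁻¹,
p_m = 3 % with 2 % intensity noise and refitted: the recovered rate agrees
with the truth within its covariance error. Three synthetic mutants whose
peaks sit between the free and bound endpoints project to their true
inactive-state fractions, and their plate-assay activities fall on the
activity–population line within the quoted r.m.s.d. The geometry stage
recovers the constructed helix separation and angle.

Individual stages are available as `methylex simulate | fit-dispersion |
csp | project | activity | geom` on your own files; see `--help` of each
subcommand for the expected CSV/peak-list columns.

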