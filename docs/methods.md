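# Methods

## Scope

`geldiff` estimates (i) the apparent diffusion coefficient D_app of a
fluorescent drug in a hydrogel channel from time-lapse intensity profiles
and (ii) the intracellular uptake kinetics of cells embedded in that gel:
per-zone uptake rates, the transport rate constant k_cell and the apparent
cell permeability P_cell. A synthetic-chip generator produces
ground-truthed image stacks with the same statistical structure, so every
stage of the pipeline is testable offline.

## Forward model and discretization

Axial drug transport is modelled as 1D diffusion, ∂C/∂t = D ∂²C/∂y², with
y = 0 at the donor-side gel interface. The fitting solver is a θ = 1/2
(Crank–Nicolson) finite-difference scheme on the interval between the
lower fit boundary (default 150 µm inside the donor interface, where the
signal is free of interface irregularities) and the gel/acceptor
interface, with

* Δy = 12.50339 µm (every 10th pixel of the 1.250339 µm lattice),
* Δt = 30 s,
* zero initial condition at t = 0 (the moment of drug addition),
* a sink condition C = 0 at the acceptor end,
* a measured, time-dependent Dirichlet condition at the lower end.

All timestamps are absolute (they include the lag t_lag between drug
addition and the first acquired frame). Requested output times are
rounded to the nearest 30 s step; the ≤15 s alignment error is recorded in
the fit report. The Dirichlet value enters at both θ-levels of each step
(t and t+Δt), the standard Crank–Nicolson treatment of time-dependent
boundary data.

**Startup damping.** At the mesh ratios used here (D·Δt/Δy² ≈ 20–120) the
Crank–Nicolson amplification factor of high-frequency modes approaches −1,
so a non-smooth start (e.g. a step boundary) would leave slowly decaying
odd–even oscillations. The first time step is therefore replaced by two
backward-Euler half-steps (Rannacher smoothing). For the smooth saturating
boundaries of real fits this changes nothing measurable; for step-boundary
validation runs it restores clean second-order behaviour. With it, the
solver matches the semi-infinite analytic solution C₀·erfc(y/(2√(Dt)))
to < 0.4% of C₀ at early times and the linear steady state to machine
precision; halving Δy and Δt moves predicted profiles by < 0.5% across
D ∈ [100, 600] µm²/s.

## The data-driven lower boundary

The boundary intensity at the lower fit boundary is measured at each frame
as the mean of the profile value at the boundary pixel and its 5 lower and
5 higher neighbours (11-point average, noise reduction). Its early shape
decides the boundary model:

* concave growth from zero, I₂/I₁ < t₂/t₁ — the first two measured values
  fix the saturating exponential I_LB(t) = I_LB,∞(1 − e^(−βt)) exactly
  (closed form when t₂ = 2t₁ via e^(−βt₁) = I₂/I₁ − 1, otherwise a
  bracketed root solve for β on [10⁻⁸, 1] s⁻¹); the exponential covers
  [0, t₂] and a linear spline through the later measured values covers the
  rest;
* linear or convex growth (tie included) — a linear spline anchored at
  (0, 0) through all measured values.

Beyond the last knot the boundary holds its last value. Saturated inputs
(I₂ ≤ I₁) cap β at the top of the bracket with a warning. The tie-break
toward the spline and the numeric concavity criterion are this package's
choices; only the qualitative rule (concave → exponential) is inherited
from the experimental procedure.

## Fit-time selection and the inverse fit

Out of the measured frames, the two fit times are the earliest pair for
which (i) the mean baseline-corrected intensity over the final 100 µm of
the fit interval is below 2% of that profile's maximum (the sink
assumption still holds) and (ii) the profile exceeds 5% of its maximum
somewhere beyond 1 mm from the lower boundary (enough developed gradient
to constrain D). Both thresholds are configurable. Fast matrices therefore
fit early frames, slow matrices later ones. If fewer than two frames
qualify the selector raises an error listing, per frame, which criterion
failed.

Baseline correction precedes fitting: either one scalar (the mean over the
100 µm of gel furthest from the donor, at the first frame) or the entire
first profile is subtracted; negative values are kept, since clipping
would bias least squares.

The single parameter is optimized as log D (keeping D positive) by a
Levenberg–Marquardt iteration over the joint residuals of both fit times
at the grid nodes: damping λ starts at 10⁻³, ×10 on a rejected step, ÷10
on an accepted one; the Jacobian is a forward difference in log D;
convergence is a relative SSE change < 10⁻⁶ between accepted iterations
(flagged unconverged after 200). The initial guess comes from the
half-maximum penetration depth, D₀ ≈ x₅₀²/(4t_a). The two fit times enter
with equal weight and no intensity scale factor is co-fitted — the
boundary condition already carries the scale of the data, and the fit is
exactly invariant under a common rescaling of measurements and boundary.

## Single-cell uptake

Nuclei are segmented once, on the maximum-intensity projection of the
NucBlue channel over the whole series: Otsu threshold (override
available), binary dilation (2 px default), distance-transform watershed
applied to connected components larger than 1.5× the median component area
(with the marker min-distance set to ~0.7× the component's equivalent
radius, so single nuclei are not split), and particle analysis; components
with equivalent radius < 3 µm are discarded. Cell positions are assumed
static, so the one ROI list is applied to every frame of both fluorescence
channels, and the per-cell trace is the mean over the dilated mask (the
dilated area also defines the cell radius r = √(A/π)).

Cells are binned into half-open 250 µm zones, [250k, 250(k+1)), measured
from the donor interface; zones 0–7 (0–2000 µm) are analyzed. Zone-mean
cellular DOX intensities are converted to concentration through the linear
calibration I = slope·C + intercept (fits are accepted into the pipeline
only when R² > 0.97; conversions outside the calibrated range are flagged
because self-quenching makes the relation sub-linear above ~25 µM). The
local zone gel concentration — taken from the axial profile with cell
masks excluded from the transverse average — is subtracted from the
cellular trace by default, because the cell mask sits inside fluorescent
gel and its raw mean reports intracellular plus matrix signal; the option
can be disabled to reproduce a raw-trace analysis.

The uptake rate per zone is the OLS slope (intercept free) of zone-mean
cellular concentration against time over the full course up to 180 min;
k_cell is the OLS slope of uptake rate against the zone gel concentration,
with one (concentration, rate) pair per zone per timepoint at 60, 120 and
180 min; and P_cell = k_cell·r/(3·60) µm/s with r the mean detected radius
of analyzed cells (override available). Because each zone contributes one
rate paired with three concentrations, within-zone concentration growth
between 60 and 180 min dilutes the regression slightly; on synthetic
ground truth this leaves k_cell biased low by roughly 5–10% under the
default conditions — an inherent property of this estimator, kept as
specified rather than redesigned.

The Stokes–Einstein utility rescales a free diffusion coefficient between
temperatures as D₂ = D₁·(T₂/T₁)·(η(T₁)/η(T₂)), with the Vogel-type water
viscosity correlation η(T) = 2.414×10⁻⁵·10^(247.8/(T−140)) Pa·s, valid for
liquid water (273–373 K). A fixed viscosity table would serve equally; the
correlation was chosen for smoothness and invertibility.

## Statistical comparisons

Two groups with raw replicate values follow a gate sequence at α = 0.05:
Shapiro–Wilk per group; if both pass, an F-test on variances chooses
between the pooled t-test (equal variances) and Welch's t-test; if either
fails, the Mann–Whitney U test. Groups given only as (n, mean, sd)
summaries skip the gates and require the t-variant to be named. Three or
more groups use Kruskal–Wallis with Dunn's post hoc of each group against
a control, Bonferroni-adjusted over the family of contrasts (the default
behaviour of the commercial package typically used for this design; the
adjustment method is recorded in the report). All p values are two-sided.
Variance comparisons report the two-sided F-test with each group's CV%.
Under a seeded Gaussian null (n = 8 vs 7) the data-driven two-group path
rejects at 4.9–5.4% over 10⁴ replicates.

## The synthetic chip generator

The generator emulates the experiment the analysis assumes: a 3 mm gel at
1.250339 µm/pixel imaged every 5 min for 3 h starting 5 min after drug
addition; a donor boundary saturating as C_∞(1 − e^(−βt)) with C_∞ = 20 µM
and β = 1/300 s⁻¹ (β = ∞ gives a step for validation); a sink at the far
end. The concentration field is computed on the native pixel lattice with
a time step ≤ 7.5 s — ten times finer in space and at least four times
finer in time than the fitting grid — so inverse fits never see their own
discretization (no inverse crime). Rendered channels:

* **dox** — the gel field through the calibration line (500 a.u./µM,
  intercept 100 a.u.; the slope leaves 16-bit headroom so a realistic,
  non-saturating acquisition is emulated), plus, per cell, a uniform disk
  over the whole cell (radius r ~ N(9.9, 0.7) µm) of added intensity
  tracking the programmed intracellular concentration
  C_cell(t) = k_cell·∫C_gel(y_cell, s) ds with k_cell = 0.016 min⁻¹ by
  default. The disk is uniform rather than peaked so that the mask-mean
  measured downstream equals the programmed concentration for any mask
  inside the cell — cell-shape rendering is not the quantity under test.
* **nucblue** — Gaussian-profile nuclei (radius 0.7r, σ = r_nuc/2) over a
  200 a.u. background, with amplitude decaying as exp(−c·∫C_cell dt),
  c = 2.5×10⁻⁴ per µM·min, which reproduces the experimentally observed
  ~30–60% depletion over 3 h depending on zone.
* **dic** — a uniform field with dark lines at the gel interfaces.

Additive i.i.d. Gaussian noise (sd 50 a.u.) is applied per pixel and the
result quantized to 16 bit. Cells are placed by rejection sampling with a
minimum separation of the summed diameters (explicit positions can be
supplied, e.g. to create touching pairs for watershed tests); identical
seeds give byte-identical stacks. The ground truth (parameters, cell
table, realized boundary, intracellular concentrations) is serialized to a
manifest.

What the generator does **not** emulate: optical sectioning and the
microscope PSF, photobleaching, cell migration or division, Poisson
(shot-noise) statistics, tile-stitching seams, and drug binding or
consumption by cells strong enough to deplete the gradient. Passing tests
therefore validate the estimators under the stated transport model and a
Gaussian detector, not robustness to those effects.

## Problem sizes and numerical tolerances used in validation

Diffusion-coefficient recovery runs on 14 frames (out to 70 min) of the
full 2400-pixel gel: noiseless recovery is ≤ 0.5% for
D ∈ {100, 250, 500} µm²/s, and the median error over 20 seeds of 5%
multiplicative noise is ~1%. The rendered end-to-end chip uses 20 cells on
a 300 µm-wide strip (37 frames, 3 h): cell detection is exact, D_app is
recovered within ~0.5%, k_cell within ~4–10% (the estimator attenuation
discussed above), and P_cell satisfies its defining relation exactly. The
type-I error simulation uses 10⁴ replicates. These sizes were chosen to
exercise the full method at the experiment's native geometry while keeping
a complete validation run in tens of seconds.

## Known limitations

* The concavity criterion and the 2%/5% fit-time thresholds are numeric
  stand-ins for qualitative experimental judgements; both are exposed as
  parameters.
* k_cell inherits a structural low bias from pairing one uptake rate with
  three concentrations per zone (see above).
* The cellular concentration is taken over the dilated nucleus mask; if
  intracellular drug is strongly compartmentalized the mask mean is a
  biased estimate of whole-cell concentration.
* Boundary detection assumes dark DIC interface lines perpendicular to the
  gel axis; manual overrides are first-class for anything else.
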