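# geldiff

Quantitative analysis of drug transport in hydrogel chips from confocal
time-lapse imaging: apparent diffusion coefficients of a fluorescent drug
(doxorubicin, DOX) in gel matrices, and single-cell uptake kinetics of
embedded tumor cells.

## Who this is for

Labs running reservoir-gel diffusion chips: a ~3 mm hydrogel channel
connects a donor reservoir (drug solution) to an acceptor reservoir
(sink), and the developing fluorescence gradient is imaged every few
minutes, together with a nuclear stain (NucBlue/Hoechst) and a DIC channel
when cells are embedded in the gel. `geldiff` turns those stacks into
apparent diffusion coefficients, per-zone intracellular uptake rates, a
transport rate constant and an apparent cell permeability, with a
ground-truthed synthetic-chip generator so the entire pipeline can be
validated without laboratory data.

## The model

**Diffusion.** Drug transport along the gel axis y is modelled by the 1D
diffusion equation ∂C/∂t = D ∂²C/∂y², solved with a Crank–Nicolson scheme
on a grid of every 10th pixel (Δy = 12.50339 µm) with Δt = 30 s. The
boundary at the acceptor side is a sink (C = 0). The boundary at the
donor side of the fit interval is taken from the data itself: the measured
intensity there (an 11-pixel average) is described over the first two
measurement intervals by a saturating exponential

    I_LB(t) = I_LB,∞ · (1 − e^(−β·t)),

fitted exactly through the first two measured boundary values (zero at
t = 0, where t includes the lag between drug addition and the first
frame), and continued by a linear spline through the later values; if the
early rise is linear or convex rather than concave, the whole boundary is
a linear spline. The single parameter D is then estimated by a
Levenberg–Marquardt fit of predicted to measured baseline-corrected
profiles at two selected time points, converged when the relative change
in the sum of squared errors drops below 10⁻⁶.

**Uptake.** Nuclei are segmented from a maximum-intensity projection of
the NucBlue channel (threshold → dilation → watershed → particle
analysis), cells are binned into 250 µm zones along the gel, and the
zone-mean intracellular DOX concentration (via a linear calibration) is
regressed against time to give an uptake rate (µM/min) per zone. Uptake
rates against the local gel concentration at 60, 120 and 180 min give the
transport rate constant k_cell (min⁻¹), and, for spherical cells of radius
r (V/A = r/3),

    P_cell = k_cell · r / (3 · 60)      [µm/s].

A Stokes–Einstein utility rescales free diffusion coefficients between
temperatures (D ∝ T/η(T), Vogel viscosity correlation for water).

## Worked example

Fit the apparent diffusion coefficient of a synthetic experiment with a
known ground truth of 250 µm²/s and realistic detector noise:

```python
import numpy as np
from geldiff import (SimulationParams, simulate_profiles, ProfileSeries,
                     GelGeometry, baseline_correct,
                     estimate_diffusion_coefficient,
                     stokes_einstein_scale, cell_permeability)

params = SimulationParams(d_true=250.0, noise_sd=50.0, seed=42)
profiles = simulate_profiles(params, params.frame_times_s[:14])
rng = np.random.default_rng(42)
profiles = ProfileSeries(y_um=profiles.y_um, times_s=profiles.times_s,
                         values=profiles.values
                         + rng.normal(0, params.noise_sd, profiles.values.shape))

geometry = GelGeometry(y_donor_interface=0.0, y_acceptor_interface=3000.0,
                       y_lower_boundary=150.0, y_upper_boundary=3000.0)
corrected = baseline_correct(profiles, mode="far_segment")
fit = estimate_diffusion_coefficient(corrected, geometry)
print(f"D_app = {fit.d_app:.1f} um^2/s  (boundary: {fit.boundary.mode}, "
      f"fitted at t = {fit.times_used[0]:.0f} s and {fit.times_used[1]:.0f} s, "
      f"{fit.n_iterations} LM iterations)")
print(f"D at 37 C from 362 um^2/s at 30 C: {stokes_einstein_scale(362, 303.15, 310.15):.1f}")
print(f"P_cell(k=0.0163/min, r=9.9 um) = {cell_permeability(0.0163, 9.9):.3e} um/s")
```

prints

```
D_app = 250.5 um^2/s  (boundary: exp_then_spline, fitted at t = 900 s and 1200 s, 4 LM iterations)
D at 37 C from 362 um^2/s at 30 C: 427.7
P_cell(k=0.0163/min, r=9.9 um) = 8.965e-04 um/s
```

The fitted D lands within 0.2% of the ground truth; the method selected
the 15 and 20 min profiles (early times, because this matrix is fast
enough for the gradient to reach 1 mm quickly while the sink end is still
dark) and classified the donor-side boundary rise as concave, hence the
saturating-exponential + spline boundary.

The same analyses are available from the shell:

```sh
geldiff simulate --config sim.json --seed 5 --out run/
geldiff extract-profiles --stack run/ --baseline none --out run/profiles.csv
geldiff fit-diffusion --profiles run/profiles.csv --out run/fit/
geldiff analyze-cells --stack run/ --out run/cells/
geldiff stats --data groups.csv --out run/stats.json
```

## Limitations

Transport is modelled as pure 1D diffusion (no convection, no binding
kinetics, no cellular consumption of the gradient); cells are assumed
static and are measured through one projection-derived ROI list; DOX
self-quenching above ~25 µM and quenching on DNA binding are flagged but
not corrected. See `docs/methods.md` for the full model description and
numerical choices.
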