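# Methods

## Model and assumptions

The synaptic cleft is treated as a flat disc of height *h* (default 40 nm)
and outer radius *S* (default 3 µm) with a central transmissive zone of
radius *R* (default 500 nm; 300 nm for the small-synapse budget examples).
Because h ≪ S, concentration gradients across the cleft height are
neglected and the diffusion equation is depth-averaged; rotational symmetry
reduces it to the radial coordinate. Vesicular release, channel fluxes and
other membrane exchange inside the active zone are folded into a uniform
volumetric source k (mol m⁻³ s⁻¹) on r ≤ R rather than a Neumann membrane
flux — equivalent for a thin cleft and much more tractable. The far field
at r ≥ S is held at a constant baseline (a large extracellular reservoir or
glial sink); a nonzero baseline is a pure additive offset throughout, since
the problem is linear in c − c∞.

Buffering by slow-moving, fast-binding molecules is reduced to an effective
diffusion coefficient D̄ = D/(1+G) with G = [B]·k_on/k_off. This is the
standard rapid-buffer approximation; it does not resolve buffer saturation
or mobile-buffer transport. Note the mixed units deliberately kept at the
interface: buffer concentration in mol/m³ (SI) but k_on in M⁻¹s⁻¹, the form
in which association constants are tabulated; the conversion factor lives
in one place (`BufferModel.G`).

All computation is SI internally (m, s, mol/m³); the reporting layer
converts to µm, ms and µM for human-facing tables.

## Closed forms

The stationary solution of the radial Poisson problem is parabolic inside
the source zone and logarithmic outside, matched in value and slope at R.
Useful consequences, all exercised by the tests: the profile depends on
the source only through K = k/D̄; the peak c(0) − c∞ = K R²(1/4 + ln(S/R)/2)
grows logarithmically with S and linearly with 1/D̄; at R = S/10 the
centre-to-zone-edge ratio is the rate-independent constant 1 + 1/(2 ln 10)
≈ 1.2171; and the rim outflow −D̄·2πSh·c′(S) exactly balances the total
release πR²hk.

The slowest relaxation mode of the homogeneous problem with a clamped rim
is J₀(ρ₁ r/S) with rate λ_min = D̄(ρ₁/S)², ρ₁ ≈ 2.4048 the first positive
zero of J₀. Roots are found numerically (McMahon bracket + Brent to
~1e-14) because they have no closed form; the tabulated 2.4048 appears
only as a test expectation. The package deliberately does not build the
full eigenfunction series for the inhomogeneous problem; instead the
space–time estimate c_stat(r)·(1 − e^(−t/τ_max)) (rise) or ·e^(−t/τ_max)
(decay) is offered, valid when the source changes slowly compared with
τ_max, and the exact time dependence is delegated to the finite-volume
solver.

## Finite-volume solver

Cell-centred uniform grid with faces at 0 and S; fluxes
F = −D̄·2πr_face h·Δc/Δr across interior faces make the scheme exactly
conservative, the zero-area centre face gives the reflecting condition for
free, and the Dirichlet rim is imposed through a mirrored ghost value so
the face value at S equals the baseline (second-order). A cell receives
the source iff its centre lies within R; with the default geometries
(R/S = 1/6 and grids that are multiples of 6) the staircase boundary
coincides with a face, and in general it washes out under refinement.
The observed convergence toward the closed form is second order in L2 away
from the rim; the relative L∞ error is first order because it is dominated
by the last cell, where the exact solution itself goes to zero linearly.

Time stepping is explicit forward Euler with dt = 0.25·Δr²/D̄ by default —
half the stability limit, making each update a convex combination, which
preserves positivity and the discrete maximum principle. Cleft problems
need at most ~10³ cells, so explicit stepping is simpler and fast enough;
no implicit option is provided. The state is checked at every save point
and the run aborts with the offending step index if values turn non-finite
or dip below the baseline.

Pulsed release: events at the stimulation frequency open the source for
`pulse_duration`; the instantaneous rate is boosted by
period/pulse_duration so the train-averaged release equals the configured
mean rate. The per-event release probability p multiplies the rate in
`expected` mode and gates each event as a seeded Bernoulli draw in
`stochastic` mode (p = 1 makes the two modes bit-identical). One integer
seed drives all stochastic decisions and is echoed in the metadata.

Uptake: ATPase-mediated transmembrane transport saturates, so the
"concentration dependent" sink is modelled as Michaelis–Menten areal flux
J_max·c/(K_m + c) with J_max = 3·10⁻⁶ mol m⁻² s⁻¹ and K_m defaulting to
10 µM, applied on both membranes (membrane area = 2× ring area; halve
J_max for a single active membrane). For c ≪ K_m this reduces to a linear
sink of conductance J_max/K_m.

A consequence worth stating plainly: with K_m = 10 µM, uptake at this
J_max can remove up to (2/h)·J_max ≈ 150 mol m⁻³ s⁻¹ everywhere in the
cleft. At conservative release rates (the ~1400 ions/s budget, k ≈ 0.2
mol m⁻³ s⁻¹, sub-µM concentrations) uptake therefore dominates and empties
the cleft almost completely. The regime in which uptake is only a modest
perturbation — concentrations well above K_m and total release well above
the saturated uptake capacity J_max·2πS² — requires k of order 10⁴–10⁵
mol m⁻³ s⁻¹ (cleft concentrations of tens of mM "total released zinc"
equivalent). The uptake comparison workflow and its tests therefore run at
k = 5·10⁴ mol m⁻³ s⁻¹ and observe probe averages a few percent to ~20%
lower with uptake on. Because the pulse duty cycle is 50%, instantaneous
probe values ride a large ripple around the mean; agreement with the
constant-release stationary profile is assessed on the average over the
last full stimulation period (within 5% at the probe radii), which is the
statement the first-order approximation actually makes.

## Ion budgeting

N = (π/6)d³·C·N_A ions per vesicle; a 40 nm vesicle holds ~20 ions at
1 mM and ~30 at 1.5 mM (the conservative band bracketing the canonical
~28), rising to ~10² at 5 mM. A 100 Hz × 1 s train at p = 0.5 with 28
ions/event releases 1400 ions, inside the expected 500–6000 envelope; the
exact parameter combinations behind those envelope endpoints are not
pinned down, so the package exposes the computation rather than asserting
the endpoints. Budgets are cumulative released ions (losses to buffers and
uptake are a separate question); counts stay fractional internally and are
rounded only for display. The equivalent volumetric source rate is
k = rate/(N_A πR²h) ≈ 0.206 mol m⁻³ s⁻¹ for 1400 ions/s at R = 300 nm,
h = 40 nm. The figure-level concentration magnitudes of the
release–diffusion model depend on k, which is a required user input — the
budget helper makes the choice explicit rather than hiding a default in
the solver.

## Indicator calibration

The sigmoid F([Zn]) = a/(b + c·e^(−d([Zn]−f))) + t is over-parameterised:
only a/b, (c/b)e^(df), d and t are identifiable. The fitter pins b = 1 and
f = 0, leaving a well-posed four-parameter problem, and reports curve-level
agreement; parameter values themselves are not comparable across fits.
Optimisation runs in log₁₀ coordinates for the positive parameters
(amplitude anchored on the observed intensity range, slope box spanning
half-rise scales from ~10 pM to ~100 µM) using seeded differential
evolution with restarts, followed by a trust-region least-squares polish;
non-convergence sets a flag and warns, never passes silently. On noiseless
synthetic ladders the refitted curve matches the generator to machine
precision; the contract tested is 1% everywhere on 0–250 nM.

Inversion is the exact algebraic inverse, valid strictly between the
asymptotes t and a/b + t; readings at or beyond an asymptote raise an
error naming the bound (250 nM standards already sit in the upper
asymptotic region of the default curve). Near saturation (d·[Zn] ≳ 12) the
inverse is numerically ill-conditioned, which is the same statement as
"outside the calibrated range".

The synthetic series generator emulates a plate-reader dilution row: a
blank plus eleven log-spaced standards from 50 pM to 250 nM, exact forward
values plus i.i.d. Gaussian read noise. It does not emulate bleaching
drift within a plate, pipetting error correlated across wells, or
indicator–chelator competition, so passing fits demonstrate recovery of
the curve family under ideal noise, not robustness to those artefacts.
Each experimental condition (calcium level, UV exposure) is calibrated
independently, which is how condition-specific offsets are absorbed.

## Numerical choices and test scales

Steady-state verification integrates to 12 τ_max (transient remainder
~6·10⁻⁶ relative) on 150/300/600-cell grids; the free-decay constant is
fitted on the window [τ, 2.5τ] of a 600-cell run started from the analytic
profile; mass-balance checks seal the rim and compare cleft content with
time-integrated release (machine precision, threshold 10⁻⁸). The
eigenvalue cross-check symmetrises the discrete operator by a √V
similarity and takes the largest eigenvalue of the resulting tridiagonal
matrix at 2000 cells (agreement within 1%). These sizes keep the whole
suite under about a minute while leaving each criterion an order of
magnitude of margin.

## Known limitations

No z-resolution, no advection, no explicit buffer PDE (only the D̄
reduction), Bernoulli-per-event release with at most one vesicle per
event, no photolysis kinetics of the caged chelator, and no claim about
free-vs-total zinc partitioning: profiles are total released solute, and
converting them to free-ion levels requires binding kinetics outside this
model's scope.
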