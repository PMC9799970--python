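# Methods

`pfwave` models the mechanics of tubulin protofilaments curling outward from
disassembling microtubule tips, and infers their stiffness and contour
length from optical-trap "wave assay" measurements, in which the curls push
a lattice-tethered bead against a force clamp and produce a brief pulse of
bead motion.

## Single-curl elastica

A protofilament curl of `N` tubulin dimers is a chain of rigid rods of
length `r = 8.2 nm`, joined by Hookean torsion springs of stiffness `κ`
(pN·nm·rad⁻¹) with a relaxed angle `θ_i = 23°` per joint. All bending
compliance is lumped into one effective spring per dimer; the model does not
resolve how strain distributes between inter- and intra-dimer interfaces or
the tubulin core, and bending is confined to the radial plane (where
cryo-electron tomography places nearly all of the shape variation at
disassembling tips).

A compressive point load `F` at the tip (the sign convention of the assay:
the trap-loaded bead opposes the outward curl) gives the per-node torque
balance

    κ (θ_n − θ_i) + F r Σ_{k≥n} cos Φ_k = 0,    Φ_k = θ_1 + … + θ_k,

which is the stationarity condition of the total potential
`½ κ Σ (θ_n − θ_i)² + F · h`, with tip height `h = r Σ sin Φ_k`. The system
is solved by continuation in `F` from the relaxed state (guaranteeing the
branch connected to the relaxed shape; multiple equilibria/snap-through are
not explored), each step using MINPACK's Powell hybrid dogleg method
followed by damped Newton polishing to a residual max-norm of 1e-10 pN·nm.
Loads requiring more than 500 continuation steps, or for which polishing
stalls, raise a convergence error. Force-deflection curves default to a
0–20 pN grid in 0.1 pN steps and are truncated at the first force where the
tip would cross the microtubule wall.

Because the equilibrium depends on `(F, κ)` only through the dimensionless
load `λ = F r / κ`, a master curve `h(λ)` is precomputed per `(N, θ_i, r)`
(λ grid 0–3, step 0.002) and rescaled for any `κ`. The whole-tip model and
the fitter use this cached path; the direct per-force solver remains the
reference and the two agree to the interpolation error (≲ 4·10⁻⁴ nm on the
default grids).

## Whole-tip contact model

Thirteen curls are arranged radially (wall radius 12.5 nm, the standard
13-protofilament geometry; configurable). The bead is an infinitely flat,
rigid, frictionless plane — its 440 nm diameter dwarfs the microtubule — 
descending along the apex direction. A curl at azimuth `φ` touches the
plane at distance `z` from the axis when `(R_wall + h) cos φ ≥ z`; contact
compresses it radially to `h = z/cos φ − R_wall`, and only the normal
component `F_single(h) · cos φ` of its radial push loads the plane. Curls
with `cos φ ≤ 0` face away from the bead and never engage. Sequential
engagement as the bead descends produces slight ripples in the
force–deflection curve whose phase depends on the tip's azimuthal rotation;
curves for the offsets `{0, π/13}` are averaged (force at matched bead
height) to represent an arbitrary rotation.

A non-integer mean curl length `n̄` (curl lengths at a real tip are set by a
kinetic balance of curling and breakage, so the fitted mean need not be an
integer) is realised as the `(1−frac, frac)` mixture of the two bracketing
integer-length tip curves. The mixture is taken over **bead height at
matched force** (equivalently, the inverted curves are mixed), not over
force at matched height: this makes the zero-force bead height the weighted
mean of the component apical heights — e.g. `0.7·9.103 + 0.3·16.758 =
11.40 nm` for `n̄ = 2.3` — which is the physically meaningful unloaded
amplitude of a population of curls of mixed length. Mixing force at matched
height would instead pin the zero-force intercept to the taller component
alone, which does not represent a population average.

One consequence of joints acting in series is that longer curls are more
compliant: the load that flattens a single curl falls with `N`
(dimensionless `λ_max` ≈ 0.40, 0.24, 0.17, 0.13, 0.11 for N = 1…5 at
θ_i = 23°). Longer curls therefore project higher and enclose more
area/work, but near mutual suppression their predicted amplitude crosses
below that of shorter curls.

## Lever geometry

The bead hangs on a ~36 nm single-antibody tether and is pressed against the
lattice at a secondary contact, so it rocks about the tether when pushed:
measured axial amplitudes exceed lateral curl heights by a leverage factor,
taken as the constant 2.0 (configurable; a force- or angle-dependent
geometric construction is deliberately not attempted). Forces convert as the
virtual-work complement, `F_lat = leverage · F_trap`, so mechanical work is
identical in both frames and fitted work outputs are frame-independent.
Setting `leverage = 1` reproduces a trap-frame fit exactly.

## Inference

`fit_model` fits `(κ, n̄)` to per-condition mean pulse amplitude vs trap
force summaries. Data are first converted to the curl frame (height =
amplitude / leverage, lateral force = leverage × trap force) and the
inverse-variance-weighted sum of squares `Σ (h_k − h_model)² / sem_k²` is
minimised with SciPy's trust-region-reflective least squares
(Levenberg–Marquardt family; TRF is used because the parameter bounds
κ ∈ [10, 1000] pN·nm·rad⁻¹, n̄ ∈ [1, 5] dimers are enforced). Defaults:
initialisation κ = 150, n̄ = 3. The parameter covariance is the
Jacobian-based `(JᵀWJ)⁻¹` scaled by the reduced chi-square (switchable via
`scale_covariance=False`), and 95% CIs use Student's t with
`n_levels − 2` degrees of freedom. Conditions are fitted independently;
pooling κ across conditions, if desired, is done by fitting the
concatenated summaries.

`line_work_analysis` performs the weighted straight-line fit `A = a − b·F`.
The area under the line, `W = a²/(2b)`, is the total mechanical work the
curls could deliver in the assay; the y-intercept `a` is the unloaded
amplitude and `a/b` the suppression force. `Var(W) = (a/b)² σ_a² +
(a²/2b²)² σ_b²`, with `a` and `b` treated as uncorrelated. A non-negative
fitted slope flags the work as undefined rather than raising.

`straightening_energy` reports `½ κ θ_i²` per interface in pN·nm, k_BT
(4.114 pN·nm at 25 °C) and kcal/mol (6.95 pN·nm each). This harmonic
per-interface figure (≈ 3.45 k_BT at κ = 176, θ_i = 23°) is the strain the
one-spring-per-dimer model itself stores; substantially larger per-dimer
lattice strain estimates circulate in the literature, but they are not
reproduced by this harmonic expression and no attempt is made to force
agreement — the package reports only what its own model computes.

## Pulse detection

Force-clamp records (200 Hz) are parameterised by the peak of the
boxcar-smoothed position (default width 25 ms; 0 disables) relative to the
mean of a baseline window (default the first 0.5 s), searched from the
baseline end to bead detachment (first drop > 50 nm below baseline) or the
trace end. The baseline SD comes from the unsmoothed baseline window, and a
pulse is accepted only if its amplitude reaches 3 × that SD — with ~2.5 nm
baseline noise this is the 6–10 nm acceptance band typical of the assay.
Max-picking over a smoothed noisy trace is slightly upward-biased (a few
tenths of the smoothed noise SD); this is inherent to peak-based
parameterisation and is shared by the synthetic round-trip tests.

## Synthetic data

The generator stands in for the instrument so the whole pipeline is testable
offline. Per-event amplitudes are drawn about the tip-model prediction at
each trap force from a zero-truncated Gaussian (event-to-event SD default
8 nm, matching per-level SEMs of ~1.5 nm at N ≈ 30 events); traces carry
Gaussian baseline noise (default 2.5 nm), a 30 ms half-cosine rise, a
plateau of 0.1–0.4 s, and a detachment step. Default trap-force levels are
1, 2, 3, 4, 6, 8 pN with 30 events per level, spanning the assay's working
range up to near suppression. One seed drives all draws and is recorded in
every output.

What the generator does **not** emulate: Brownian bead dynamics and servo
response, force-dependent event censoring at the acquisition stage,
drift/low-frequency noise, and any non-Gaussian tail of the true
event-amplitude distribution (only means/SEMs of the real data are known).
Passing closure tests therefore demonstrates internal consistency of the
pipeline under these assumptions, not fidelity to every property of real
records.

A statistical caveat documented here deliberately: at force levels where the
predicted amplitude is within ~2 SD of zero (trap forces ≳ 2 pN for short
bovine-like curls with SD 8 nm), the zero-truncation inflates the mean of
simulated events well above the model prediction. Fitting the untruncated
model to such means is misspecified and biases the inferred stiffness
upward, so confidence-interval coverage of the generating parameters
degrades when the design includes near-suppressed levels. The same
mechanism — small pulses preferentially falling below the detection
threshold — inflates measured means in the real assay; the censoring tests
quantify it. Users fitting synthetic (or real) data should either restrict
force levels to the clearly measurable regime or interpret the fitted
stiffness as conditional on the censoring.

## Numerical and degenerate-input choices

Torque-balance residual tolerance 1e-10 pN·nm (max-norm); master-curve λ
step 0.002; tip-curve bead-height step 0.02 nm; mixture inversion on a
2048-point force grid. Trap forces beyond a curve's range give amplitude 0
and a `suppressed` flag rather than an error. Mean curl lengths above 5
dimers warn (the model is characterised for 1–5) but proceed. Datasets need
≥ 3 force levels to fit the two parameters and ≥ 2 for the line fit;
non-positive SEMs with replicated events, duplicate force levels and
negative amplitudes/forces are rejected with explicit errors. All units are
nm / pN / pN·nm / radians internally; configuration files accept degrees.

## Problem sizes used in the checks

The equilibrium-vs-minimisation cross-check runs 100 random chains of up to
4 joints; the work-integral check uses a 2.5 pN curve at 0.0025 pN steps;
recovery and censoring studies use 100–120 replicates of 30-event-per-level
datasets. These sizes give Monte-Carlo error comfortably below the asserted
tolerances while keeping the default suite fast.
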