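# Methods

## Scope and structure

`biosos` simulates suspension cultures of iPSC aggregates across three
scales: single-cell metabolic kinetics (stochastic reaction counting),
intra-aggregate transport (quasi-steady spherical diffusion), and
population-scale aggregation (a coagulation–growth population balance).
The modules are usable independently; `biosos.assembly.simulate` couples
them with one-way coupling from aggregation to metabolism (aggregation is
assumed insensitive to the metabolite state over the simulated horizons).

## Units

Lengths in µm, time in hours, concentrations in mM, per-cell fluxes in
nmol per 10⁶ cells per hour (the metabolic-flux-analysis convention), and
diffusivities in µm²/h. Two conversion constants link the flux scale to
concentrations (see `biosos.units`): a per-cell flux v weighted by a cell
density G (cells/mL) changes bulk concentration at G·v·10⁻⁹ mM/h, and
changes the cell's own intracellular concentration at
v·10³·3/(4π·7.5³) ≈ 0.566·v mM/h (a 7.5 µm cell radius throughout). The
volumetric-rate factor γ = 3×10⁶/(4π·ε·7.5³) follows the convention
γ·A = 10⁶ with A = ε·(4π/3)·7.5³; multiplying N·v·γ by 10⁻³ yields mM/h,
which is the scale the shell solver consumes.

## Population balance model

State: the density φ(x, t) over aggregate size x = R³ on a uniform radius
grid (default 7.5–600 µm at 1 µm; explicit Euler at Δt = 0.1 h; a CFL check
rejects steps that would advect more than one grid cell). The coagulation
kernel treats φ as a *fraction* density (φ dx sums to 1 over aggregates),
which is the normalization its calibrated constants
(k = 1.26×10⁻³, k₁ = 1.94×10⁻⁴, a = 0.806) assume; the solver normalizes
internally and restores the caller's absolute scale on output, so
coalescence dynamics depend on the shape of the distribution only.

Numerics: pairwise coalescence events are binned with a fixed-pivot split —
the merged size x_i + x_j is distributed over the two bracketing grid nodes
with weights that conserve aggregate number and mass exactly per event
(mass conservation under pure coalescence is the solver's headline
property; mass beyond the top node is assigned there mass-conservatively
and logged). Gompertz growth (M = 9.71×10⁶ µm³, α_G = 5.72×10⁻³ h⁻¹,
clamped to zero above M) advects the density with a conservative first-order
upwind scheme, which conserves aggregate count exactly and tracks the
Gompertz characteristic to a few percent on the default grid. Negative
densities (not observed on the default grid) would be clipped with the lost
mass logged.

The radius transform uses the calculus Jacobian φ_R(R) = 3R²·φ(R³); a
`jacobian="printed"` switch reproduces a published 2R² variant for audit
(it does not preserve total counts). Break-up and shrinkage are excluded
(not observed in the cultures the kernel was calibrated on).

## Reaction–diffusion micro-environment

Aggregates are partitioned into equal-width shells (default 15 µm ≈ two
cell diameters, N_ℓ = ceil(R_ℓ/15)); cells and concentrations are
homogeneous within a shell. With piecewise-constant volumetric rates ρ
(signed, mM/h) the steady spherical diffusion equation has the per-shell
closed form c(r) = u + ρ(R_out² − r²)/(6D), chained inward by continuity at
shared interfaces; for uniform ρ the chain telescopes to the exact
whole-sphere solution, and for non-uniform ρ it matches a finite-difference
solve of the full problem to well under 1% in the tested regimes (the FD
solver ships as a validation oracle only). Two printed-form discrepancies
are handled explicitly: D belongs in the denominator (dimensional analysis;
a `literal_eq5` switch reproduces the D-multiplied form for audit), and the
sign convention keeps ρ signed so nutrients (ρ < 0) rise center→surface and
wastes fall.

Effective diffusivity D = (ε/τ)·D^a with ε = 0.27, τ = 1.5 and packaged
aqueous diffusivities for glucose, lactate, glutamine, glutamate, alanine,
serine, ammonium and CO₂ (order 10⁶ µm²/h, from standard aqueous values).
Concentrations clamp at zero; shells whose level falls below 10⁻³ of the
bulk are flagged depleted. The flux↔profile fixed point is solved by damped
Picard iteration (damping 0.6, relative tolerance 10⁻⁶, ≤100 iterations;
loop gain is well below 1 for the packaged kinetics, so convergence takes
10–20 iterations). Intracellular pools do not diffuse between shells.

## Single-cell stochastic metabolic network

The packaged network has 32 metabolites (8 extracellular, 24 intracellular
pools) and 38 reactions covering glycolysis, a two-reaction lumped pentose
phosphate pathway, the TCA cycle, anaplerosis (pyruvate carboxylase) and
cataplerosis (malic enzyme), glutamine/glutamate/alanine/serine/aspartate
metabolism, transport steps, and a biomass precursor drain. CO₂ is treated
as freely exchanged (extracellular) so decarboxylation has an outlet.

Reaction counts over an interval are independent Poisson draws with
intensity v_j·Δt·Ω. The system size Ω sets event granularity: the
single-cell default Ω = 500 makes a nominal 200-flux-unit reaction produce
10⁴ expected events per 0.1 h step (small tau-leap error); the bulk update
uses Ω_bulk = 10⁶ events per mM of culture volume. Rates are frozen at the
start of each counting interval (tau-leaping); recursive interval halving
guards against negative copy numbers in `step_cell`, and the coupled
simulator advances intracellular pools on 10 substeps per 0.1 h interval
because pool turnover (minutes) is faster than the interval. For any left
null vector w of the stoichiometric matrix, w·ũ is conserved along every
sample path.

### The default rate-law family

The true single-cell flux responses of these cultures were calibrated
elsewhere and are not public; the flux model is therefore a pluggable
interface (`FluxModel.rates(state) → v ≥ 0`), and the packaged default is a
documented stand-in: irreversible Michaelis–Menten in every consumed
substrate with optional product inhibition (reversible steps split into
forward/reverse components), parameters in the network CSV. Magnitudes
follow published mammalian/iPSC culture ranges: glucose uptake ~10²
flux units with an effective Km of 8 mM (the lumped uptake response must
stay sensitive over the 5–17.5 mM range spanned by the monolayer
calibration data), lactate yield ≈ 1.6–1.8 per glucose (Warburg-like),
glutamine uptake ~10¹, biomass ~10⁰–10¹. Product inhibitions are placed so
every pool is bounded: producers saturate off as their product accumulates
while consumers saturate on, which yields stable pools of a few mM over
72 h simulations. Two structural calibration notes: the TCA C4/C5 pool
needs a cataplerotic exit (malic enzyme) to balance anaplerotic and
transaminase inputs, and the mid-cycle steps carry no product inhibition
(their consumers' capacity alone bounds them) to avoid artificial
backpressure deadlocks.

## Coupled simulator

Per Δt interval: (1) group densities G_ℓ^(n) = M_ℓ(1−ε)((R^(n))³−(R^(n−1))³)/R₀³
come from static radius groups or from the evolving population balance
solution sampled at the interval; (2) quasi-steady shell profiles are
solved once against the interval-start bulk; (3) each (group, shell,
reaction) channel draws Poisson counts at the volume-scaled intensity
G·v·Δt (in bulk-concentration units, Ω_bulk) to update the bulk in batch
mode, while each shell's representative cell draws counts at the
single-cell scale (Ω = 500) to advance its intracellular pools — the
single-cell scale is used because a representative cell's noise must not
depend on how rare its group is. Expectations of both updates equal the
deterministic dynamic flux-balance ODE at the same discretization
(`deterministic_ode_trajectory` mirrors it exactly, including the frozen
extracellular state per interval). Held-constant mode pins all (or a named
subset of) bulk species. Monolayer mode sets every aggregate to a single
7.5 µm cell — one shell, no gradients — and reproduces the deterministic
model in replicate mean. Replicates derive independent seeds from a master
seed via `numpy.random.SeedSequence.spawn`, so results are reproducible and
independent of execution order.

## Heterogeneity analysis

The metabolite-increment mean and variance of a group follow the Poisson
identities μ = Σ_n Σ_j v̄ Δt N_ij and σ² = Σ_n Σ_j v̄ Δt N_ij²/Ω (an
empirical mode estimates both from replicate draws); group variances add
because aggregates are modeled as independent, and RSD = σ/μ. Flux
standardization z-scores per-reaction group-average fluxes across size
groups with the L−1 sample standard deviation. Health classification uses
local *extracellular* quasi-steady concentrations (the thresholds —
glucose < 2.5 mM, lactate > 40 mM — are media levels), weighted by shell
cell counts. The inner/outer heterogeneity index is the sum over reactions
of |v(innermost shell midpoint) − v(outermost shell midpoint)|; per-reaction
ratios are also reported (undefined ratios for zero outer flux are flagged
and excluded).

### Study designs

*Health sweep*: deterministic — solve the quasi-steady profile at given
bulk glucose/lactate for each radius and classify. When bulk glucose is
below 2.5 mM the surface itself is unhealthy and consuming profiles only
fall inward, so all radii report 100%.

*Inner/outer heterogeneity study*: each radius is simulated as a culture of
identical aggregates at 10⁶ cells/mL — not literally one aggregate — so the
non-held bulk species (glutamine, serine, ammonium, …) draw down on a
realistic culture timescale while glucose (25 mM), lactate (5 mM) and
alanine (0.1 mM) are held constant. Per-cell fluxes "at" a time point are
averaged over the trailing 1 h of trajectory and over the 30 replicates
*before* differencing, so the index measures the systematic spatial
gradient rather than the single-cell sampling floor. Under the packaged
kinetics the 240:60 µm index ratio at 24 h is ≈10–13× (the gradient scale
grows roughly with R²). The index is nearly stationary between 24 and
48 h (growth factor ≈0.8–1.1): with Michaelis–Menten pools the intracellular
state and the micro-environment equilibrate well before 24 h, so the
packaged stand-in does not reproduce the temporal doubling that the
original calibration's slower intracellular dynamics produce. This is a
known limitation of the default flux model, not of the framework — a user
supplying a calibrated flux model inherits its temporal behavior.

*Yield–heterogeneity size sweep*: one batch culture is grown from a
2×10⁵ cells/mL single-cell inoculum with the population balance coupled in
(group densities M_ℓ(t) track the evolving distribution); at each
measurement time the biomass increment over a 1 h window is summarized per
size group analytically (Poisson identities) and empirically (default 100
sampled windows). Because the group variance carries M_ℓ, rare large
aggregates have small group intensity and hence large RSD: mean biomass
falls and RSD rises with radius across the upper tail of the distribution.
The packaged sweep covers 75–135 µm at 48 h — the range the packaged
aggregation kinetics actually populate from a single-cell inoculum — rather
than the 30–300 µm of larger-scale studies; below the distribution's mass
mode the rarity argument reverses, so the monotone trade-off statement is
specific to the upper tail.

## Synthetic data and what tests show

`biosos.fixtures` generates everything the tests and examples consume: toy
networks with closed-form dynamics (one- and two-step extracellular chains,
an intracellular two-pool cell), point-mass and lognormal initial aggregate
densities, and the study presets. The toy fixtures make the
stochastic/deterministic consistency checks exact oracles; the full network
is a literature-plausible stand-in, so passing tests demonstrate the
correctness of the mechanistic machinery (conservation, Poisson identities,
PDE agreement, monotone trends) and the qualitative biology (core
starvation, size-dependent heterogeneity, yield trade-off), not predictive
accuracy for any particular cell line. Real cultures additionally feature
oxygen limitation, pH, shear, fed-batch feeding and cell death, none of
which are modeled.

## Numerical choices and degenerate inputs

Tolerances: quasi-steady fixed point 10⁻⁶ relative (damping 0.6); PBM mass
conservation verified to <0.5% over 72 h; FD oracle agreement <1%. Problem
sizes in the shipped studies (30-replicate heterogeneity runs, 100-window
size sweeps, 500-replicate monolayer consistency checks, 72 h PBM horizons)
were chosen to resolve the reported quantities on a single CPU in minutes.
Degenerate inputs: zero-flux models short-circuit to flat dynamics;
single-shell aggregates have unit inner/outer ratios; zero means make RSD
undefined (reported NaN with a warning); zero spread flags standardized
fluxes as 0; empty densities and non-increasing grids are rejected at
construction. All clamping (negative bulk, negative pools) is counted on
the trajectory (`clamp_events`) and logged.
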