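# Methods

## Cell model

The membrane model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
action potential: fast Na⁺, transient-outward, ultrarapid/rapid/slow delayed
rectifier and inward-rectifier K⁺ currents, L-type Ca²⁺ current, Na⁺/K⁺
pump, Na⁺/Ca²⁺ exchanger, background and sarcolemmal-pump Ca²⁺ currents, and
a two-compartment sarcoplasmic reticulum. Constants and rate equations
follow the standard published formulation; the resting initial state is the
published quiescent steady state. Two implementation details:

- the removable singularities of the rate expressions (e.g. the m-gate α at
  V = −47.13 mV) are replaced by their analytic limits, with the same
  10⁻¹⁰ mV guard bands as the reference transcription;
- the SR release gates u/v respond to the junctional flux variable Fn
  through extremely steep sigmoids; their exponent argument is clipped to
  ±700 (deep saturation) so `exp` stays in range. The scalar oracle used in
  the tests applies the identical guard.

Disease and drug states are expressed **only** through multiplicative
conductance factors (`CurrentScaleSet`): AF electrical remodeling
(I_Na ×0.90, I_to ×0.30, I_CaL ×0.50, I_Kur ×0.50, I_K1 ×2.0, I_NCX ×1.4),
fibrotic myocytes (I_K1 ×0.5, I_CaL ×0.5, I_Na ×0.6), and high-dose (15 μM)
flecainide (I_to ×0.95, I_CaL ×0.95, I_Kr ×0.70, I_Na ×0.55). Flecainide is
a static block: rate-dependent (use-dependent) Na-channel kinetics are out
of scope, so the drug's anti-arrhythmic effect at fast rates is likely
underestimated. Fibrotic nodes by default carry the fibrosis factors
*composed onto* the tissue preset (product of both sets); set
`fibrosis_composed=False` to use the fibrosis factors alone. Pumps,
background currents and I_Ks have scale slots but no preset modifies them.

Integration: Rush–Larsen exponential update for all 15 gates, forward Euler
for voltage and concentrations. dt defaults to 0.02 ms for production and
0.05 ms in the test suite; the planar-wave CV moves by <2% when dt is
halved from 0.05 (verified in the suite).

## Tissue model

Monodomain reaction–diffusion on a triangulated sheet. Space: linear (P1)
finite elements with a per-triangle conductivity tensor
`D = d_t I + (d_l − d_t) f fᵀ` built from averaged node fibers; the
stiffness matrix is paired with a lumped mass matrix, which yields exact
conservation (row sums zero) and natural zero-flux boundaries. Triangles
containing an ablated node are excluded from the integration domain, so
lesion interfaces are no-flux walls and ablated nodes carry no state — the
"membrane potential set to zero" reading of ablation is implemented as
electrically inert scar rather than a literal 0 mV clamp, which would act
as a depolarizing source. Time: operator splitting, reaction step then
explicit diffusion step, with automatic sub-stepping when dt exceeds 90% of
the Gershgorin stability bound of `M⁻¹K`.

Optionally each node carries a diffusivity factor (default 0.5 on fibrotic
nodes in the pipeline) so fibrotic patches conduct slowly as well as being
ionically remodeled.

Conduction-velocity calibration launches a planar wave from one sheet edge
(a deliberately strong, wide stimulus — −80 pA/pF over a 1.5-mm band — so
capture does not depend on the electrotonic load at high diffusivity) and
bisects d_l until the CV between two probes at 30%/70% of the sheet width
matches the target within tolerance. CV grows monotonically with d
(≈ √d), so bisection on a (0.02, 0.6) mm²/ms bracket converges in a few
evaluations; the bracket auto-expands before failing.

Stimulus convention: amplitudes are in pA/pF, depolarizing negative. The
default tissue stimulus is −22 pA/pF for 2 ms ≈ 2× the measured 2-ms
diastolic threshold (≈ −11 pA/pF) of the baseline cell.

## Synthetic anatomy

Patient CT/electroanatomical data are replaced by a flat rectangular sheet
that preserves the topological essentials: four disc-shaped PV sleeves in
two vertically adjacent pairs (each pair encirclable by one lesion ring), a
tagged sheet border standing in for the mitral/atrial boundary, fibers
x-aligned with circumferential deflection around each ostium. The mesh is a
structured right-triangle grid with seeded interior jitter
(edge SD/mean ≈ 0.19); grid spacing is chosen so the mean edge length
(diagonals included) hits the target — 400 μm desk default, 235 μm as the
full-scale preset. The **sleeve region** is defined as the whole encircled
antrum (every node inside the ring locus, split between the pair's veins by
proximity): with that convention, applying a gap-free ring partitions
active nodes exactly into sleeve vs. body components, which is the
isolation property the lesion tests check.

Fibrosis is a seeded clustered label field: cluster centers drawn uniformly
from the atrial body, grown to a fixed radius (3 mm default) until the
target fraction of body nodes is labeled, then trimmed to the exact count.
Defaults: 20% density — a mid-range fibrotic burden for a persistent-AF
atrium; real fibrosis architecture (micro-channels, transmural gradients,
voltage-map correlation) is not emulated.

Lesions: stadium-shaped rings around each PV pair (centerline at
pv_radius + 2 mm from the inter-vein segment; line width
max(2 mm, 2.5 edges)); gaps are arc-length windows of fixed width (2 mm
clinical default, four per model — the two straight-segment midpoints of
each ring, i.e. opposite sides); focal discs for highest-DF ablation.
Filling all gaps is node-identical to the gap-free ring by construction.

## Wave-dynamics analysis

- **DF**: periodogram (linear detrend, Hann taper) of the per-node voltage
  over the analysis window, peak frequency in 1–20 Hz, ties to the lower
  bin. Nodes with no activation in the window are masked.
- **COV-DF**: 100 × sample SD / mean of per-node DF over a region. The
  "high-DF" population is read as *all* valid nodes of the region
  (default); a top-decile variant is available behind a flag.
- **AFCL**: mean of consecutive activation intervals pooled over region
  nodes. Activation = upward crossing of −40 mV with a 50-ms refractory.
- **Smax**: per node, in-fibrillation (DI, APD₉₀) pairs are collected from
  the activation sequence (DI = interval − preceding APD); the
  mono-exponential `APD = A − B e^(−DI/τ)` is fitted by separable least
  squares (linear in A, B for fixed τ; τ profiled on a geometric grid and
  refined by golden section — deterministic and cheap enough to fit every
  node); Smax = (B/τ)·e^(−DI_min/τ) at the smallest observed DI. Nodes with
  fewer than 5 pairs are masked; an exactly flat APD–DI relation
  short-circuits to Smax = 0. A single-cell S1–S2 restitution protocol is
  retained as controlled ground truth for validating the estimator.
- **Outcome**: `terminated` if no non-ablated node activates in the final
  2 s of the observation; else `converted_to_at` if the pooled
  cycle-length CV < 10% *and* COV-DF < 5% (an operationalization of
  "regular tachycardia" — both thresholds are config parameters); else
  `sustained_af`. Defragmentation = terminated or converted.
- **Wave-breaks at gaps**: instantaneous phase from a delayed-coordinate
  embedding (v(t), v(t−τ)), τ = 10 ms, origin at the window mean; a phase
  singularity is a ±2π winding around an elementary triangle, gated on the
  embedding radius of all three vertices (≥10 mV) because the phase is
  undefined near the origin and flickers during spatially uniform
  repolarization. A corridor transit is a paired activation of PV-side and
  LA-side sentinel nodes within 30 ms, its direction given by the order; a
  break is a singularity within 5 mm of the gap within 50 ms after a
  transit.

## Pipeline and protocols

Study timeline per scenario: build → fibrosis → CV calibration (on the
pristine substrate) → pre-induction lesions (none / complete PVI /
PVI-with-gaps) → decremental burst pacing (8 beats per cycle length from
200 ms down to 120 ms in 10-ms steps = 11,520 ms scheduled at full scale;
the 10-ms decrement is the unique value consistent with that printed total)
→ observation → late-window analysis. Rescue interventions (fill the
wave-breaking gaps, ablate the highest-DF site away from the gaps, or apply
flecainide to every non-ablated node) are applied to an ongoing-AF
checkpoint at the intervention time and the run resumes; resuming with *no*
intervention is bit-identical to an uninterrupted run (the checkpoint
carries the full state and the activation-detector refractory memory).

Pacing site: a 1.5-mm disc in the atrial body just outside the
left-superior PV ring — a stand-in for clinically mapped trigger sites,
which are unavailable. PV sleeves carry the same ionic preset as the body
by default (switchable). Induction "success" is not separately
operationalized; an episode is simply classified at observation end.

Desk-scale defaults (50 × 50 mm at 400 μm, 10-s observation, 5–9-s
analysis window, reduced beats per level) exist because the full protocol
(4–5 × 10⁵ elements × 32 s) is a cluster job: the pure-NumPy kernel steps
~10³ nodes at ≈1 μs per node per 0.05-ms step. The test suite scales
further down (20–30-mm sheets, ≤5-s observations) to fit CI budgets.

## What a green test run does and does not establish

The suite establishes: exact preset percentages and protocol arithmetic;
equivalence of the vectorized kernel with an independent scalar CRN
transcription to 10⁻⁹; gate boundedness/positivity through APs; planar-wave
propagation ordering, CV measurement/calibration/convergence; the
isolation, gap-conduction and block-permanence properties of lesion sets at
test resolution; analytic recovery for the DF, COV and Smax operators; and
bitwise determinism of tissue runs and end-to-end CSV outputs.

It does **not** establish clinical fidelity of the cohort-level findings:
desk-scale sheets are below the fibrillatory wavelength of this cell model
(CV·APD ≳ 20 mm even with AF remodeling), so self-sustained multi-wavelet
AF — and hence meaningful defragmentation-rate comparisons between complete
PVI and PVI-with-gaps — requires the full-scale preset on larger geometry.
Consistent with that, cross-field spiral-wave initiation on 25–40-mm sheets
produces a wave-break that dies within one rotation; the phase-singularity
detector is therefore validated against a constructed rotating spiral field
(core localized to one triangle, one detection per sample, consistent
chirality) plus planar-wave and quiescent negative controls from real
simulations.

## Numerical and degenerate-input choices

- APD measurement: from the max-dV/dt instant to the crossing of
  rest + (1−f)·amplitude (f = 0.9 ⇒ APD₉₀), linear interpolation between
  samples; the resting level is the minimum over a 5-ms pre-upstroke
  window (the max-dV/dt sample itself already sits on the upstroke at 0.5–
  1-ms sampling). Constant traces raise a no-action-potential error.
- The CRN restitution curve still rises ≈2.5% between DI = S1 CL and
  DI = 2× S1 CL at a 1,000-ms S1 (slow recovery processes); asymptote
  checks in the tests use a 3% band for this reason.
- IDW interpolation: Shepard weights d^(−p), p = 2; a node within 10⁻⁹ mm
  of a sample takes the sample value exactly.
- COV uses the sample SD (n−1). DF ties break toward the lower frequency;
  highest-DF ties break toward the lower node id.
- All random operations take explicit seeds (numpy `default_rng`); meshes,
  fibrosis fields and full simulations are bit-reproducible.

## Known limitations

Single-layer flat sheet (no 3-D LA surface, wall thickness, endo/epi
bilayer, or bi-atrial coupling); fibrosis is a statistical stand-in, not
image-derived; flecainide lacks rate-dependent Na-block kinetics; no
autonomic/ganglionated-plexi effects; electrogram-based (bipolar) DF is not
modeled — all analyses read the transmembrane voltage directly.
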