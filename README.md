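# atrialab

A desk-scale computational laboratory for studying how pulmonary-vein
isolation (PVI) gaps shape atrial-fibrillation (AF) wave dynamics.

Catheter ablation of AF electrically disconnects the pulmonary-vein (PV)
sleeves from the left atrium, but the lesion lines often reconnect through
millimetre-scale gaps, and the mechanism by which such gaps sustain AF is an
open question. `atrialab` provides the simulation and analysis machinery to
ask that question *in silico*: a human atrial cell model with AF-remodeling,
fibrosis, and drug presets, a monodomain tissue solver on synthetic LA-like
sheets, virtual ablation lesion sets (complete PVI, PVI with 2-mm gaps, gap
fills, focal lesions), and the wave-dynamics metrics used to compare them.
It is aimed at cardiac-electrophysiology modelers and methods developers who
want a self-contained, fully seeded substrate — patient imaging and
electroanatomical maps are deliberately *not* required.

## The model

**Cell.** The Courtemanche–Ramirez–Nattel (CRN) human atrial action
potential: 21 states (V, 15 gates, 5 concentrations). Disease and drug
electrophysiology enter as multiplicative conductance factors:

| preset | modification |
|---|---|
| `af_remodeling` | I_Na −10%, I_to −70%, I_CaL −50%, I_Kur −50%, I_K1 +100%, I_NCX +40% |
| `fibrosis` | I_K1 −50%, I_CaL −50%, I_Na −40% (vs. normal cells) |
| `flecainide` (15 μM) | I_to −5%, I_CaL −5%, I_Kr −30%, I_Na −45% |

Presets compose multiplicatively (fibrotic tissue in an AF-remodeled atrium
carries the product of both sets).

**Tissue.** Monodomain reaction–diffusion,
`∂V/∂t = −I_ion/C_m + ∇·(D∇V)`, with a fiber-aligned anisotropic tensor
`D = d_t I + (d_l − d_t) f fᵀ`, discretized with P1 finite elements on a
triangulated sheet and integrated by operator splitting (Rush–Larsen gates +
explicit diffusion). Ablated nodes are removed from the domain — a permanent
conduction block. The diffusivity is calibrated by bisection so a planar
wave runs at a prescribed conduction velocity (CV).

**Analysis.** Per-node dominant frequency (DF; periodogram peak in 1–20 Hz
over a 6-s window), COV-DF (100·SD/mean of per-node DF), mean AF cycle
length (AFCL), and Smax — the maximal slope of the APD restitution curve
`APD = A − B·e^(−DI/τ)`, evaluated at the shortest observed diastolic
interval. Outcomes are classified as `terminated`, `converted_to_at`
(regular, spectrally uniform rhythm), or `sustained_af`; "defragmentation"
is termination-or-conversion. Wave-breaks at PVI gaps are scored from phase
singularities (±2π winding of the delayed-embedding phase around a mesh
triangle near the gap exit after a corridor transit).

## Worked example

```python
import numpy as np
from atrialab import (build_idealized_la, make_pvi_lesions, fill_gaps,
                      apply_lesions, preset_scales, run_tissue, StimulusEvent)

# 30 x 30 mm sheet, four PV sleeves, ~700-um edges
mesh = build_idealized_la(30, 30, target_edge_um=700, pv_radius_mm=2.5, seed=31)
lesions = make_pvi_lesions(mesh, with_gaps=True, gap_width_mm=2.0)
print(lesions.gap_ids())
# ['left:g0', 'left:g1', 'right:g0', 'right:g1']

# keep a single 2-mm gap, ablate, pace the atrial body twice
one_gap = fill_gaps(lesions, lesions.gap_ids()[1:])
m = apply_lesions(mesh, one_gap)
pts, act = m.points, m.active()
cand = np.flatnonzero(act & (m.region == 0))
c = cand[np.argmin(np.linalg.norm(pts[cand, :2] - [15, 2], axis=1))]
disc = cand[np.linalg.norm(pts[cand, :2] - pts[c, :2], axis=1) <= 1.5]
stims = [StimulusEvent(tuple(disc), 2 + 250 * k, 3.0, -80.0) for k in range(2)]
res = run_tissue(m, preset_scales("af_remodeling"), stims, 800.0,
                 dt_ms=0.05, d_longitudinal=0.12, equilibrate_ms=200.0)

pv_left = np.flatnonzero(np.isin(m.region, [1, 2]) & act)
pv_right = np.flatnonzero(np.isin(m.region, [3, 4]) & act)
print(np.mean([len(res.activation_times[i]) > 0 for i in pv_left]))   # 1.0
print(np.mean([len(res.activation_times[i]) > 0 for i in pv_right]))  # 0.0
```

The two printed fractions say that every node of the PV pair behind the
remaining 2-mm gap was activated by the body pacing (conduction re-enters
through the gap), while the fully encircled pair on the other side recorded
no activation at all — the complete lesion line is a conduction block.

The same experiment end-to-end, with CV calibration, the decremental
AF-induction ramp (200→120 ms), observation, and the metric table:

```bash
atrialab simulate --seed 1 --intervention pvi_gap --outdir out/
atrialab compare --seed 1 --interventions none,pvi_gap,cpvi --out comparison.csv
```

`comparison.csv` holds one row per scenario (classification, mean AFCL,
mean DF overall and intra/extra-PV, COV-DF, mean Smax, per-gap wave-break
counts) plus Δ-columns against the first row.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: it builds the seeded
fibrotic substrate, calibrates conduction to 0.40 m/s, runs the PVI-gap and
complete-PVI scenarios through induction, observation and wave-dynamics
analysis, prints the comparison table, and writes the results JSON to
`--out`.

## Scale

Defaults are desk-scale (mm-level sheets, thousands of nodes, seconds of
simulated time — minutes of CPU). `ScenarioConfig.paper_scale()` switches to
the full protocol (235-μm target edge, 8-beat pacing ramp totalling
11,520 ms, 32-s observation, 17–23-s analysis window), which is a
cluster-sized job. See `docs/methods.md` for what desk scale does and does
not establish.
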