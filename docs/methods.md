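# Methods

## The index and its physical model

The instantaneous wave-free ratio (iFR) is the ratio of distal coronary
pressure to aortic pressure averaged over the diastolic wave-free period,
measured at rest; values ≤ 0.89 indicate a hemodynamically significant
stenosis. `ctifr` estimates this index from centerline geometry with a
steady, rigid-wall, Newtonian solve at diastolic conditions. The steady
solve is a surrogate for the wave-free window: microvascular resistance is
approximately constant there, so a single solve at the diastolic aortic
root pressure stands in for averaging a pulsatile signal over the window.
No pulsatile waveform is simulated, and the wave-free window timing
(25% into diastole to 5 ms before its end) is a property of invasive
signal processing, not of this model.

The 3D lumen is reduced to a 1D centerline: each segment is a polyline of
positions and lumen radii (mm), resampled at uniform arclength. Pressure
is marched downstream from the inlet with two loss terms per step:

* **Viscous**: ΔP = 8πμQ·ds/Ā², Ā = (A_in + A_out)/2. For a uniform tube
  this telescopes to the exact Poiseuille drop 8μLQ/(πr⁴) at any step
  size; on tapers the error is O(ds²).
* **Expansion** (post-stenotic pressure-recovery loss): Borda–Carnot,
  K_e·(ρ/2)·Q²·(1/A_throat − 1/A)², with K_e = 1 by default. The loss is
  accumulated over each maximal monotone-expanding run of the area
  profile, telescoped from the run's starting (throat) area. Summing the
  naive per-step form (1/A_in − 1/A_out)² instead would make the total
  loss proportional to the step size on a smooth recovery and vanish
  under refinement; the run-telescoped form is grid-convergent and
  reduces exactly to the per-step formula when the expansion happens in a
  single step. `step_pressure_drop` exposes both behaviours through its
  optional throat-area argument.

Junctions impose pressure continuity (children start at the parent's
terminal pressure); flow reversal and collaterals are unsupported — trees
are strictly diverging, so every step drop is non-negative and the
pressure ratio is non-increasing along any root-to-leaf path.

If the marched pressure reaches zero the solver raises a
degenerate-physics error naming the offending point: with flow prescribed
(see below), a sufficiently tight throat demands a pressure gradient the
inlet pressure cannot supply. This is a genuine validity boundary of
fixed-flow boundary conditions, not a numerical artifact; real coronary
flow through a near-occlusive lesion collapses instead.

## Boundary conditions

* **Inlet flow** from perfused myocardial mass, Q = c·M^α mL/min with
  c = 3.41, α = 0.75 — an allometric ¾-power form giving ≈ 246 mL/min of
  total resting coronary flow for a 300 g heart. Both coefficients are
  configurable; they set the flow scale, not a patient fit.
* **Outlet split** by Murray's law over outlet lumen diameters,
  Qᵢ = Q·dᵢ^γ/Σdⱼ^γ with γ = 3. An outlet's diameter is twice its mean
  radius over the distal 3 mm, damping discretization noise. Internal
  segment flows are sums of descendant-outlet flows, so conservation at
  junctions is exact by construction.
* **Inlet pressure**: the diastolic aortic root pressure (mmHg,
  converted at 133.322 Pa/mmHg) — the natural reference pressure for a
  diastolic index.
* **Hyperemic mode** multiplies all flows by h (default 3.0, the typical
  adenosine-induced increase). It exists to produce an FFR-like
  surrogate (read at the same point, cutoff 0.80); the resting index
  itself never needs it.

## Geometry and severity conventions

Stenoses are cosine-profiled: radius times 1 − (DS/100)·(1+cos 2πu)/2
over the lesion window, so severity is exact at the center and the
shoulders are untouched. Percent diameter stenosis is measured as
(1 − r_min/r_ref)·100 with r_ref the maximum radius within 10 mm proximal
to the minimum — a deliberate, testable convention; clinical DS readings
have no single standard reference rule. Bifurcation lesions are not
modelled. Default resampling step 0.5 mm (≲ CT voxel scale); halving it
changes the index by well under 0.001 on the standard test vessel.

The sensor sits 30 mm downstream of the lesion throat (the conventional
"~3 cm distal" wire position), following the largest-flow child at
branchings and clamping at the vessel end; both offset and anchor are
configurable.

## The synthetic cohort

The generator stands in for CCTA reconstruction and invasive measurement,
emulating a single-center stable-CAD study population: one target vessel
per patient; LAD/LCX/RCA proportions 0.72/0.11/0.17; diameter stenosis
uniform on 30–90% (the angiographic inclusion window); LV mass
N(120, 20²) g truncated above 50 g with vessel-subtended fractions
LAD/LCX/RCA = 0.5/0.2/0.3; diastolic aortic pressure N(80, 8²) mmHg
truncated above 40.

Vessel anatomy: proximal radii 1.9/1.7/2.0 mm (LAD/LCX/RCA), lengths
120/90/115 mm, three (LAD) or more generally seed-drawn side branches
with daughter/parent radius ratio 0.8 — large enough that branches steal
flow the way septals and diagonals do. Disease is not a single clean
focal lesion: the index lesion's length is drawn U(12, 25) mm
(focal-to-diffuse), each vessel gets a diffuse narrowing rate
U(0.004, 0.008) mm radius per mm, and 40% of vessels carry a secondary
mild lesion (DS 20–50%). These choices anchor the emulated population to
the kind of cohort such indices are validated in, where moderate
anatomic severity already carries measurable physiologic loss and
anatomy alone discriminates imperfectly.

"Invasive" measurements are the computed indices plus independent
Gaussian noise (σ_iFR = 0.02, σ_FFR = 0.03 by default; 0.046 reproduces
the published iFR-agreement scale), clipped into (0, 1]. Vessels whose
resting or hyperemic solve is degenerate (see above) are recorded at a
floor index of 0.05 with a `clipped` flag — they are unambiguously
"significant", and the flag preserves the information that the model's
fixed-flow regime was exceeded. Seeding uses one master seed spawning
independent per-vessel child streams, so row i is invariant to the cohort
size.

What passing tests on this cohort do **not** show: the generator shares
the solver's own physics, so cohort-level agreement statistics validate
the pipeline's plumbing and the statistics' implementations, never the
physiological accuracy of the index against real patients. Clinical
quantities that depend on the real 36-vessel dataset (correlation
coefficients, AUCs, Bland–Altman biases) are therefore exercised as
structural properties and orders of magnitude, not reproduced.

## Statistical battery

* Positivity is cutoff-inclusive (value ≤ cutoff) everywhere —
  classification, cohort labels, and decision curves.
* Confidence intervals on proportions are Clopper–Pearson exact binomial.
  Point estimates round half-up to whole percent for display.
* AUC is the Mann–Whitney statistic with ties counted ½, computed from
  DeLong placement values; its SE and the paired AUC comparison use the
  DeLong (1988) covariance. Degenerate variances are flagged undefined
  rather than silently zeroed. ROC orientation is fixed: lower index ⇒
  positive, score = 1 − index.
* Bland–Altman: bias ± 1.96·sd of paired differences (sample sd, n−1).
* Correlation comparison is independent-samples Fisher r-to-z; a Steiger
  dependent-correlation variant is provided but not used by default.
* Decision curves evaluate the fixed ≤-cutoff classifier:
  NB(pt) = TP/n − (FP/n)·pt/(1−pt) on the default grid
  pt ∈ {0.01, …, 0.99}, against treat-all and treat-none.

## Problem sizes and numerical choices

The test suite and acceptance script run cohorts of 30–200 vessels at the
0.5 mm step — a 200-vessel cohort (two solves per vessel) completes in
about a second. Ties in ROC tests are induced deliberately by rounding
scores to 2 decimals. Config files are TOML; CLI flags override config,
config overrides defaults; every CLI run logs its resolved configuration
and seed, and CSV/JSON writers use fixed float formats so identical
inputs give byte-identical outputs.

## Known limitations

* 1D reduced-order physics: no secondary flows, curvature or entrance
  effects, no eccentric/irregular lesion morphology; K_e = 1 is a generic
  expansion coefficient. The solver interface is drawn so a 3D solver
  could replace `solve_pressure_field` without touching the rest.
* Fixed-flow boundary conditions overestimate losses at extreme severity
  (no autoregulatory or stenosis-limited flow reduction), hence the
  documented degenerate regime near total occlusion.
* The mass–flow coefficients, subtended-mass fractions and noise models
  are literature-scale defaults, not patient calibrations.
* Synthetic cohorts cannot validate clinical accuracy (see above).
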