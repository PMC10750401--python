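# Methods

`pacenet` simulates heart-rate autonomic modulation by a sinoatrial node
(SAN) organized as loosely connected modules of tightly coupled pacemaker
cells on a small-world network. Two modules are built in as the reference
system: a lower-rate module (LRM) whose cells have a strong membrane clock
(g_CaL = 0.52 nS/pF) and a weak Ca clock (P_up = 9 mM/s), and a
higher-rate module (HRM) with the opposite balance (g_CaL = 0.30 nS/pF,
P_up = 12 mM/s). Both points sit close to the silent/firing bifurcation
border of the single cell, which is what makes the system steerable: the
LRM leads in the basal and cholinergic (ChR) states, the HRM takes over
under beta-adrenergic (βAR) stimulation, and under ChR the HRM stops
firing altogether (dormancy).

## Single-cell model

Each cell is a rabbit central-SAN coupled-clock model: a Hodgkin–Huxley
style membrane clock (I_CaL, I_CaT, I_Kr, I_Ks, I_to, I_sus, I_f, I_st,
I_NaK, Na/Ca exchange, background Na and Ca currents, plus the
ACh-activated K current I_KACh in the cholinergic state) coupled to a
sarcoplasmic-reticulum (SR) Ca clock (SERCA uptake into the network SR,
diffusion to the junctional SR, and ryanodine-receptor (RyR) release into
a small subsarcolemmal space, where it drives inward Na/Ca-exchange
current during diastole). The state vector has 29 entries: membrane
potential, 14 gates, 4 Ca compartments, 4 RyR Markov states and 6 buffer
occupancies. Intracellular Na and K are held constant.

The equation set follows the published rabbit central-cell formulation
(membrane kinetics of the Kurata-lineage central cell; Markov RyR with
luminal-Ca-dependent gating; SERCA uptake with K_up = 0.6 µM). The
archived machine-readable reference for that model was not available when
this package was built, so the constant set was reconstructed from the
literature and then anchored to the published behavior of the two module
parameter points rather than verified constant-for-constant. Two
quantities were treated as the anchoring degrees of freedom:

- **I_CaL activation midpoint** `V_dL_half` = −15.5 mV. This places the
  silent/firing border so that (0.30 nS/pF, 12 mM/s) fires slowly and
  (0.52 nS/pF, 9 mM/s) fires at the basal rate, both near the border, as
  the reference behavior requires.
- **RyR trigger sensitivity** `k_oCa` = 100 mM⁻² ms⁻¹. This makes
  diastolic SR Ca release regenerative (the subspace-Ca feedback loop
  gain exceeds 1 once the SR reloads), which is the essence of a working
  Ca clock; with a substantially weaker trigger the SR settles into a
  continuous-leak equilibrium and the Ca clock is silent.

Both values are ordinary `CellParameters` fields; everything else is the
standard constant set. With these anchors the isolated basal rates are
~2.9 Hz (LRM point), ~2.7 Hz (HRM point) and ~2.9 Hz (default cell), and
the (g_CaL, P_up) map shows the expected bordered structure.

Because the reference implementation could not be executed here, the
equation set is guarded by regression tests (a frozen derivative vector
and a frozen 10-s basal cycle length of this implementation), a zero-flux
sanity limit, an exact-vs-tabulated consistency check, and the
published-behavior checks above — not by term-by-term comparison with the
archived model.

## Autonomic states

The basal state applies no scaling. The stimulated states are
single-scalar families: an intensity s multiplies the deviation of every
effector from unity, so calibration is one-dimensional (bisection,
1% rate tolerance).

- **βAR** (intensity s): P_up ×(1+s), g_CaL ×(1+0.4s), g_Ks ×(1+s),
  k_oCa ×(1+7s). The strong Ca-clock component (SERCA and RyR
  sensitization, as produced physiologically by PKA phosphorylation of
  phospholamban and RyR) is what lets the HRM, with its larger P_up,
  overtake the LRM. The intensity is calibrated so an isolated HRM cell
  fires at the top of the physiological range (3.9 Hz).
- **ChR** (intensity s): I_KACh conductance 0.006·s nS/pF (with weak
  inward rectification), g_CaL and P_up ×(1−0.1s). The intensity is
  calibrated so an isolated LRM cell fires at the lowest regular
  (non-arrhythmic) rate, targeting 1.7 Hz; the same intensity silences
  the isolated HRM cell. When the target lies beyond the single-cell
  silence edge, the calibrated intensity backs off that edge by 15% so
  the coupled module — whose collective silence threshold sits below the
  single cell's — stays in the firing regime. The cholinergic steady
  state settles over tens of seconds (slow SR-load adaptation), so
  calibration measurements use 30-s runs with a 14-s discard, and ChR
  tissue runs use 16 s with an 8-s discard.

These compositions are this package's calibrated formulation of the two
stimulated states; the intensity scalar is fitted, the composition ratios
are fixed design choices. Modes report `calibrated: true` in all output
metadata.

## Network generator

Cells are scattered in 3D (Gaussian clouds, SD 2 length units) around one
attractor point per module (module centers 10 units apart). Edge
probability is a saw-shaped function of distance: a tall short-range peak
per module, `A·exp(−d/λ_within)` with A = 0.9, λ_within = 1.2, for
same-module pairs, and a low long tail `B·exp(−d/λ_between)` with
B = 0.0022, λ_between = 6 for cross-module pairs. Proposals are visited
in sorted pair order from a seeded generator and rejected once either
endpoint reaches the degree cap (5). A triadic-closure pass then closes
open same-module triangles with probability 0.2 (neighboring cells in
packed tissue tend to share neighbors), which carries the high clustering
of the small-world architecture. Connectivity is repaired by joining the
smallest component to the rest through the spatially closest low-degree
pair, which keeps repair edges local and stray cross-module bridges rare.
The reference realization has ~1100 edges (degrees 1–5), ~7 inter-module
bridges, and a small-world coefficient σ = (C/C_r)/(L/L_r) of about 4.5–7
across seeds (C_r, L_r from 20 same-n same-m uniform random graphs; since
such sparse graphs are almost never connected, L_r is measured on each
realization's largest component; the ensemble metrics are computed
through igraph, which matches the networkx definitions to rounding).
A degree-preserving rewiring ensemble is available as an option.
Scaled-down reference networks (for fast tests) shrink both modules and
rescale B so the bridge count stays proportional to the cell count.

## Tissue integration

Every node runs the cell model with its module's parameters; every edge
injects Ohmic gap-junctional current (V_j − V_i)/R with R = 3750 MΩ per
connection (the published per-connection resistivity, read as a lumped
per-edge junctional resistance; the coupling term is normalized by each
cell's C_m, so one edge at a 100-mV voltage gap injects ~0.8 pA/pF). All
cells advance synchronously by fixed-step forward Euler, default
dt = 0.005 ms (RK4 is available); gate kinetics and exchanger
exponentials are pre-tabulated on a 0.02-mV grid and linearly
interpolated inside a compiled kernel, which is what makes 485-cell,
multi-second simulations take minutes on one core. AP upstrokes (−20 mV
crossing, 50-ms refractory) are detected online at full step resolution;
voltage traces are recorded at a coarser stride (default 0.1 ms). Every
cell starts from the same late-diastolic state (the first seconds of
every run are discarded, so initial values only need to lie in the
oscillator's basin); optional seeded per-cell jitter is off by default.

## Analysis

Per-cell cycle lengths come from successive upstrokes in the
post-transient window; cells with fewer than two upstrokes count as
silent. Module aggregates weight cells equally ("among cells"); silent
cells are reported through the firing fraction, not the mean. Leadership
is a majority vote over beats: all upstrokes are merged, split into beats
at gaps longer than half the median cycle length, and within each beat
the module with the earlier median upstroke leads; the lead delay is the
mean inter-module median gap. The rate range is the min/max leader-module
rate across autonomic states, rounded to 0.1 Hz. Firing classification:
silent (<2 upstrokes), chaotic (cycle-length CV > 0.05, or any cycle
longer than 3× the median), regular otherwise. The CV threshold is a
design choice (the reference figure gives none) separating the mosaic
skipped-beat region from regular firing.

## Sensitivity maps

One isolated-cell simulation per pixel over (g_CaL, P_up), pixel size
0.0025 nS/pF × 0.2 mM/s as published; the full grid is 97 × 61 = 5917
pixels over the default extents g_CaL ∈ [0.30, 0.54], P_up ∈ [0.2, 12.2]
(the published figure's extents are not recoverable from its text, so
extents are configurable). Pixels run as one uncoupled batch, 12 s per
pixel with a 2-s discard by default; a blow-up flags the pixel instead of
failing the sweep. Borders are pixel-boundary contours chained into
polylines. Tests use a 5×-thinned 20 × 13 grid at 10 s per pixel.

## Problem sizes used by the test suite and the acceptance script

The basal tissue check runs at the full published size (485 cells,
8 s, dt = 0.005 ms) in both the suite and `scripts/acceptance.py`; the
acceptance script also runs ChR (16 s) and βAR (8 s) at full size. The
test suite runs the two stimulated states on the 100-cell scaled network
and thins sensitivity grids 5×; these sizes are the package's standard
test problem sizes and are asserted at the tolerances stated for them.

## What the generator and tests do and do not show

The synthetic networks emulate modular, sparsely bridged SAN
architecture with plausible degree statistics; they are not fitted to an
imaged connectome, and real SAN tissue adds heterogeneous cell
properties, spatial gradients, additional cell types and atrial loading
that this model deliberately omits. Passing tests therefore demonstrate
the *mechanism* — rate-range widening and leading-pacemaker shift from
module specialization near criticality — not a quantitative prediction
for any real SAN.

## Known limitations

- The cell model is a literature reconstruction anchored to published
  behaviors, not a constant-for-constant verified copy of the archived
  reference; absolute cycle lengths inherit that uncertainty (a few
  percent in the basal and βAR states).
- The cholinergic slowing this cell model can sustain while staying
  regular bottoms out near 2 Hz for an isolated LRM cell (the silence
  transition is abrupt, with a clean rhythm right up to the edge), and a
  coupled module runs faster than the isolated slow limit because cells
  mutually advance each other's diastolic depolarization. The calibrated
  cholinergic intensity therefore includes a 15% back-off from the
  single-cell silence edge so the coupled tissue stays in the firing
  regime, and the cholinergic tissue cycle length comes out near
  ~465 ms (leader rate ~2.1 Hz) rather than the published deep-bradycardia
  value (585 ms, 1.7 Hz). Stronger suppression silences the whole module
  instead of slowing it further.
- Forward Euler at dt = 0.005 ms is the reference integrator
  (dt-halving changes cycle lengths by <0.5%); stability degrades above
  roughly dt = 0.02 ms.
- Intracellular Na/K are fixed, so very long simulations do not show
  slow ionic drift; the slow ChR transient reflects SR-load adaptation
  only.
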