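# Methods

`rootsim` simulates the growing *Arabidopsis* root apex as a
two-dimensional vertex model — an axial bisection of the tissue in which
cells are polygons, wall segments are edges shared between neighbours,
and growth is symplastic (no cell ever slides past another).  On top of
the mechanical core sit exchangeable developmental rule sets (the twelve
catalogue models), a hormone reaction–transport layer, and a kinematics
toolkit that judges simulated roots the way experimental kinematic
studies judge real ones.

## Mechanical core

Every cell carries a target area `A_T`; every wall segment is a linear
spring with rest length `L_T`.  The tissue energy is

    H = λ_A Σ_i f(A_i, A_T,i)  +  λ_M Σ_j s_j (l_j − L_T,j)²

with two area-term variants: the absolute form `f = (A − A_T)²` (`EQ1`)
and the normalized form `f = ((A − A_T)/A_T)²` (`EQ2`, the default).
The normalized form makes cells with equal *relative* growth deficits
contribute equally regardless of size, so a 15 µm meristematic cell and
a 200 µm elongating cell pull on the energy with the same weight; the
variant `(A − A_T)²/A_T` is available behind the same switch
(`EQ2_ALT`) but no shipped configuration uses it.  Walls aligned with
the growth axis enter the spring term scaled by `vertical_scale`
(default 0.2, i.e. five-fold softer), the 2-D stand-in for strongly
anisotropic wall extensibility: cells elongate axially with little
resistance while their width stays constrained.

The energy is minimized by Metropolis Monte Carlo node displacement:
each sweep trials every active node once, in random order, with a
uniform displacement of at most `step_size` (1 µm) per axis; downhill
moves and ties are always accepted, uphill moves with probability
`exp(−ΔH/T)` (default `T = 0.1`).  λ_A = 50, λ_M = 1 and `T` are
calibration choices that make a 10 % area deficit (ΔH ≈ 0.5 per affected
move) decisively downhill while leaving enough thermal noise to escape
shallow local minima.  Three additions keep the discrete tissue
well-posed:

* **Growth advection predictor.**  A developed elongation zone demands
  tip displacements of tens of µm per 30-min step, far beyond what
  `sweeps × step_size` of random motion can deliver.  Before each sweep
  block, the axially integrated expected elongation (from per-cell
  relative target-area deficits, binned along the axis) is applied to
  every free node as a deterministic predictor; Monte Carlo then only
  resolves local imbalances.  Because the predictor's y-map is monotone
  but not affine, slanted walls can in rare geometries be driven to
  cross; the predictor therefore validates every ring afterwards and
  bisects its amplitude (1, ½, ¼, 0) until the mesh stays simple.
* **Legality-checked trials.**  A trial move is rejected outright if it
  would invert or self-intersect any incident cell polygon — symplastic
  tissue cannot fold.  This matters because division surgery may leave
  nodes within a fraction of a µm of each other (see below).
* **Rigid mature tissue.**  Nodes all of whose incident body cells are
  mature (MZ) or columella/QC are excluded from trials.  Their target
  areas are frozen, so trialling them would only let differentiated
  tissue random-walk into degenerate shapes; physically, mature walls
  are rigid.  They still translate coherently via the predictor.

After every simulation step all rest lengths are reset to the realized
wall lengths ("plastic yielding"), so spring energy cannot accumulate
as cells elongate; the spring term acts within a step, not across
steps.

## Grid construction and division surgery

Two builders are provided.  `build_root_grid` makes the regular starter
grid: `n` files of rectangular cells, the shootward node row fixed (the
upward anchor that forces growth rootward), the three rootward rows
flagged as the non-dividing, non-growing columella/QC block.  The
standard 12-file grid has three 15 µm outer files per side flanking six
7.5 µm inner files.  `build_developed_grid` emulates a root that has
already been growing: each file is subdivided independently into rows
with heights drawn uniformly over one sizer doubling (12–24 µm), giving
a brick-wall pattern in which division phases are desynchronized from
the start.  Spatially regulated models (8–12) start from it, mirroring
the long preparatory phase such models need before their readouts are
meaningful; cell-autonomous models (1–7) start from the minimal regular
grid of one stem row over the QC block.

Cell division inserts a horizontal wall at the area-bisecting chord
(found by bisection on the clipped-polygon area).  The two chord
anchors are inserted into the lateral walls *of both adjacent cells*,
keeping the shared-wall topology exact; anchors within 0.3 µm of an
existing node reuse that node instead of creating a sliver.  Daughters
inherit chemicals and target area proportionally to area (chemical
conservation is exact by construction), both increment the division
counter, both keep the release clock, and `initial_width` (used by GA
production) is re-frozen at birth.

## Developmental rules

Cells in wall contact with the QC block are stem cells: release clock
and division counter pinned to zero, dividing at the pre-set frequency.
A daughter that loses contact starts its clock at the release step.
Zone progression is strictly one-way (STEM → DZ → EZ → MZ).  The rule
slots are: division (timer with per-file cell-cycle times and uniform
noise resampled each cycle, or sizer with per-file area thresholds and
noise), DZ exit (counter, timer, ruler distance, auxin two-threshold,
SHY2 threshold), EZ exit (timer, ruler, lower auxin threshold, GA
dilution threshold) and growth (constant target-area increment,
relative zone-dependent rates, or layer-driven with passive followers
whose `A_T` is reset to `A` each step).  When a cell satisfies both a
transition and a division in one step the transition wins and the
division is suppressed.

Reference parameter choices where the sources leave them open: cell
cycle time 900 min; DZ-exit timer 4 × CCT = 3600 min (which yields
exactly three post-release divisions under the transition-first
tie-break); DZ relative growth 0.023/step for timer models (ln 2 per
cycle, so cell sizes are stationary across divisions) and 0.02/step for
sizer models, with ten-fold acceleration (0.2/step) in the EZ of the
ruler models; sizer thresholds 360/180 µm² for outer/inner files with
±25 % uniform threshold noise (a ~14 % CV, in line with measured
size-at-division variability).

## Hormone transport and the cross-talk network

Walls are thin membranes of thickness `d = 1 µm`; no separate apoplast
compartment is modelled.  The flux from cell a to b across a wall of
interface length `L_w` is

    J = (D/d + k_import) L_w (c_a − c_b)
      + k_export L_w (PIN_ab c_a − PIN_ba c_b)

with `c = amount/area` — an a-polar part (diffusion plus symmetric
AUX/LAX-type import) and a polar PIN part with per-face carrier
densities.  The `reverse_fountain` layout sends auxin rootward through
the inner files, laterally outward through the cap, shootward through
the outer files and laterally inward again, closing the reflux loop.
Auxin sources: external influx through the shootward walls of the inner
files (with export through the outer epidermal walls), production per
area, production per cell, or a columella/QC-localized production that
anchors the apical maximum to the tip; first-order degradation
throughout.

Within a step the geometry is frozen and the transport operator is
linear, so species advance by backward-Euler sub-steps (sparse LU).
The implicit update is unconditionally stable — at the reference
permeabilities the per-cell rates reach ~500/min, which an explicit
scheme could only handle with ~10⁴ sub-steps — and it conserves mass
exactly in closed systems because the transport matrix has zero column
sums, and preserves non-negativity because `I − hM` is an M-matrix.

The cross-talk network (model 12) couples four species: auxin is
produced in the cap (2 × 10³ AU/min per QC cell), transported by the
reflux loop (D = 300, import 100, export 1200 µm/min, PIN density 4)
and degraded at 0.1/min, giving a tip-anchored apical maximum with a
~100 µm decay length that travels with the growing tip.  Cytokinin is
produced everywhere at a rate repressed by auxin (half-repression at
20 AU), diffuses slowly (100 µm²/min) and turns over at 0.02/min, so
its concentration is low in the auxin-rich tip and rises to a plateau
shootward.  SHY2 is cell-local: production saturating in cytokinin,
degradation basal plus auxin-stimulated; its concentration rises from
~2 at the tip to ~5 at the plateau and the DZ→EZ transition fires at
3 AU.  SHY2 above ~2.5 AU also represses the cell's PIN densities
(smooth Hill factor, exponent 6), reproducing the switch from polar to
a-polar transport at the transition zone.  GA is produced in dividing
cells proportionally to their width at birth and conserved afterwards,
so elongation dilutes it; the EZ→MZ transition fires when GA drops
below 1 AU.  All numeric constants of this network are package
defaults chosen to place the SHY2 crossing mid-meristem in the
reference state; the *direction* of the source-perturbation effects
(stronger auxin source → larger division zone, stronger cytokinin
source → smaller) is a structural property of the feedback loop, not of
the particular constants, and is what the tests assert.

The division-zone extent is read out as the position where the rolling
majority of cells (ordered axially) stops being STEM/DZ — robust
against single straggler cells that advect shootward before crossing
the threshold.

## Kinematics

All analysis runs on per-cell tabular snapshots (`snapshot_frame`),
also loadable from CSV.  Areal strain rate is the relative area change
between consecutive snapshots; growth potential is `A/A_T`.  Profiles
are smoothed by local-linear Gaussian-kernel regression on a regular
grid (default 10 µm spacing, 40 µm bandwidth), which reproduces
constants and straight lines exactly.  Velocity profiles track cell
centroids between snapshots, with daughters merged through the lineage
map across divisions; replicate profiles are pooled into 25 µm bins
(mean ± sd, empty bins reported as missing).

The uniform-strain violation score samples axial positions over the
tissue; at each position and consecutive-snapshot pair it takes the
spread (max − min) of the relative elongation rates (per hour, from
cell axial extents, daughters merged) of all cells whose span covers
the position, averages over the trailing persistence window (default
300 min) and over positions with at least two comparable cells.  The
score is exactly zero for spatially uniform relative growth.  The
conformity threshold (default 0.02 h⁻¹) and window are exposed
parameters — there is no canonical numeric boundary between
"short-lived" and "persistent" differences.

The two-fold size-range statistic detrends epidermal cell lengths by
the smoothed length profile (so the steep elongation-zone gradient is
not mistaken for per-position spread), forms windowed max/min envelopes
of the normalized lengths (50 µm window, at least 4 cells) and reports
the ratio of the kernel-smoothed envelopes per position.  For a
steady sizer population the expected value is the two-fold division
span.  Note a sampling caveat quantified during development: with only
4–8 epidermal cells per window, even an ideal fully decorrelated
two-fold population yields windowed max/min ratios inside [1.6, 2.4] at
only ~40–85 % of positions, and semi-synchronized cohorts released from
the stem niche periodically narrow the local spread further; the
median per-position ratio is the stable summary (1.6–2.3 in ruler/sizer
runs), while the band fraction fluctuates between snapshots.

Steady state is detected on the organ length series as the earliest
time from which the elongation rate stays within a relative tolerance
of its terminal value; exactly linear series are steady from the start
and exponential series never are.  `realism_report` bundles the three
checks (steady state, smooth profile with approximately two-fold range,
uniform-strain conformity) into one JSON-serializable verdict.

## What the synthetic data do and do not show

The generators (regular and developed grids, the two-file
constant-strain trajectory, the linear length series) provide exact,
controlled inputs: conservation, symmetry and closed-form checks are
meaningful to machine precision, and rule arithmetic (cohort sizes,
exit times) is exercised under exactly the stated conditions.  They do
not emulate curved root outlines, 3-D volumetric dilution, realistic
wall rheology, cell-wall loosening chemistry or measurement noise of
image-based kinematics, so passing tests show internal consistency of
the model family, not agreement with any particular experimental root
beyond the qualitative features built into the rules.

## Numerical choices and degenerate inputs

Chemistry sub-step 0.5–2 min (backward Euler; smaller only where a test
compares against a closed form); mechanics 30-min steps with 3–8 sweeps
depending on the run; snapshot cadence 90 min.  Division of a
columella/QC cell, zero bandwidths, empty windows, reversed time pairs
and missing-signal rules raise typed errors.  Mesh degeneration (any
self-intersecting polygon or a cell under 1 µm²) aborts a run with the
partial trajectory attached — for rule sets that violate uniform strain
this is the scientifically expected outcome, and the CLI exits with a
distinct status code for it.  Problem sizes in the shipped tests (12 ×
4 or 12 × ~16-cell grids, 40–76 simulated hours, ten replicate seeds
for the perturbation experiment) were chosen so the full suite runs on
a single CPU at desk scale.

## Known limitations

No T1/T2 topological rearrangements (intentionally: symplastic tissue),
no formative/asymmetric divisions, no root cap development, no
gravitropism or waving, no viscoelastic walls, no intracellular
compartments or ARR-level signalling detail.  The cross-talk constants
are defaults, not fitted values; quantitative zone sizes should not be
compared against measured roots, only the qualitative structure and the
perturbation directions.
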