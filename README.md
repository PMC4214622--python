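# rootsim

A vertex-based simulator of symplastic growth in the *Arabidopsis*
root tip, with a kinematic analysis toolkit for judging which growth
regulation mechanisms can produce realistic roots.

## The scientific problem

The root apex elongates by coordinated cell division (in the meristem)
and cell expansion (in the elongation zone), while all cells remain
glued to their neighbours through shared walls.  That symplastic
connectivity imposes a hard constraint — the *uniform longitudinal
strain rule* (ULSR): all points at the same distance from the tip must
elongate at the same relative rate, or the tissue distorts.  Which
regulatory schemes satisfy this rule?  Pre-programmed cell-autonomous
timers and counters?  Cell-size sizers?  Positional signals
("rulers")?  Morphogen gradients read through thresholds?  Or hormonal
cross-talk between auxin (promoting proliferation) and cytokinin
(promoting differentiation) routed through the transcription factor
SHY2 and PIN transporters?

`rootsim` implements a family of twelve such models on a common
mechanical substrate and provides the kinematic instruments — cell
length/velocity/strain-rate profiles along the axis, steady-state
detection, a quantitative ULSR-violation score — to compare their
output against the signatures of real root growth.

## The model in brief

The tissue is a 2-D polygonal cell grid (nodes, edges, cells, shared
walls).  Cell *i* wants area `A_T,i`; wall *j* is a spring of rest
length `L_T,j`.  The energy

    H = λ_A Σ_i ((A_i − A_T,i)/A_T,i)² + λ_M Σ_j s_j (l_j − L_T,j)²

is relaxed by Metropolis Monte Carlo node moves (downhill always,
uphill with probability `exp(−ΔH/T)`); growth-axis walls are softened
(`s_j < 1`) so cells elongate axially.  Growth rules raise `A_T`,
division rules insert horizontal walls that bisect the cell area,
clock rules tie stem-cell identity to contact with the quiescent
centre (QC), and zone rules move cells one-way through
meristem → elongation → maturity.  Hormones live on the same grid:
wall fluxes combine a-polar (diffusive/importer) and polar
(PIN-mediated) terms, and the model-12 network couples auxin,
cytokinin, SHY2 and GA with the canonical reverse-fountain PIN layout.
See `docs/methods.md` for the full account.

## Worked example

Run the synchronous timer model (model 2: cells released from the QC
divide three more times at a 900-min cell cycle, then accelerate) and
ask when the first cohort leaves the meristem and how large it is:

```python
from rootsim import model_config, run_model

cfg = model_config(2, duration_h=76.0, seed=1)
cfg.mech.sweeps_per_step = 4
traj = run_model(cfg)

ev = traj.events
exits = ev[(ev.event == "transition") & (ev.detail == "DZ->EZ")]
first = exits.time.min()
print("first acceleration at", first / 60.0, "h")
print("cohort size:", (exits.time == first).sum())
```

prints

```
first acceleration at 75.0 h
cohort size: 96
```

96 = 12 files × 2³ descendants of the first released row: with the two
initialization stem cycles (at 900 and 1800 min) and three post-release
divisions, the exit timer fires at 900 + 3600 min = 75 h for all of
them at once — the stepwise, clone-synchronous growth that makes purely
cell-autonomous regulation unrealistic.  The spatially regulated models
behave differently; for instance

```bash
rootsim run --model 8 --hours 40 --seed 0 --out runs/m8
rootsim analyze --traj runs/m8 --out runs/m8/analysis
```

writes `realism.json` with the three realism checks (steady organ
growth, smooth two-fold cell-length band, ULSR conformity) for the
ruler/sizer model, plus `profiles.csv` and `ulsr.json`.

The same CLI exposes `rootsim fixture` (canned synthetic inputs),
`rootsim sweep` (steady auxin gradients under transport-parameter
scans) and `rootsim config` (canonical per-model configuration files).

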