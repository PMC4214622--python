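"""The twelve canonical growth-regulation models and the simulation driver.

Each model couples the same mechanical core (polygonal cells relaxed by
Metropolis moves against target areas) to a different regulatory rule
set:

====== ============================ ==================== =============== ==========
model  DZ exit                      EZ exit              division        growth
====== ============================ ==================== =============== ==========
1      counter                      timer                timer           constant
2      timer                        timer                timer           linear
3      counter                      timer                timer           linear
4      timer                        timer                timer + noise   linear
5      counter                      timer                timer (variant) linear
6      counter                      timer                sizer (uniform) linear
7      counter                      timer                sizer           linear
8      ruler                        ruler                sizer           linear
9      ruler                        ruler                sizer           linear (+auxin field)
10     auxin threshold              auxin threshold      sizer           linear
11     layer-specific auxin thr.    layer-specific thr.  sizer           linear (layer-driven)
12     SHY2 threshold               GA threshold         sizer           linear
====== ============================ ==================== =============== ==========

Simulation step structure (default 30 min per step): update release
clocks -> zone transitions -> growth rules on target areas -> chemistry
sub-steps -> division checks and surgery -> mechanical relaxation with
plastic rest-length reset -> bookkeeping/snapshot.  Cell-autonomous
models (1-7) start from the minimal grid of one stem row over the
columella/QC block; the first two stem division rounds play the role of
the initialization divisions that shrink the starter cells.  The
spatially regulated models (8-12) start from a taller grid standing in
for an already-developed young root.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import regulation as reg
from .core_mesh import (
    DegenerationError, Mesh, Role, Zone, build_developed_grid, build_root_grid,
    divide_cell_horizontal, snapshot_frame, standard_column_widths,
)
from .mechanics import MechParams, relax
from .regulation import (
    AuxinThresholdExit, ConstantIncrement, CounterExit, GaThresholdExit,
    LayerDrivenGrowth, RelativeGrowth, RuleConfig, RulerExit, Shy2ThresholdExit,
    SizerDivision, TimerDivision, TimerExit, layer_driven_follow,
    resample_noise, should_divide, update_clocks, zone_transition,
)
from .transport import TransportParams, assign_pin_layout, step_chemistry

#: expected Table-style rule names per model (dz_exit, ez_exit, division, growth)
MODEL_TABLE = {
    1: ("counter", "timer", "timer", "constant"),
    2: ("timer", "timer", "timer", "linear"),
    3: ("counter", "timer", "timer", "linear"),
    4: ("timer", "timer", "timer", "linear"),
    5: ("counter", "timer", "timer", "linear"),
    6: ("counter", "timer", "sizer", "linear"),
    7: ("counter", "timer", "sizer", "linear"),
    8: ("ruler", "ruler", "sizer", "linear"),
    9: ("ruler", "ruler", "sizer", "linear"),
    10: ("auxin_threshold", "auxin_threshold", "sizer", "linear"),
    11: ("auxin_threshold", "auxin_threshold", "sizer", "layer_driven"),
    12: ("shy2_threshold", "ga_threshold", "sizer", "linear"),
}

CCT = 900.0            # reference cell cycle time, min
N_COLUMNS = 12
OUTER_FILES = (0, 1, 2, 9, 10, 11)
INNER_FILES = (3, 4, 5, 6, 7, 8)


@dataclass
class ModelConfig:
    model_id: int
    n_columns: int = N_COLUMNS
    n_rows: int = 4
    column_widths: list = None
    row_height: float = 15.0
    grid_kind: str = "regular"      # or "developed" (randomized row phases)
    body_length: float = 240.0      # µm of body tissue for developed grids
    mech: MechParams = field(default_factory=MechParams)
    rules: RuleConfig = field(default_factory=RuleConfig)
    transport: TransportParams = None
    pin_scheme: str = "apolar"
    pin_density: float = 1.0
    source_mode: str = "MIXED"
    species: tuple = ()
    chem_burnin_min: float = 0.0
    duration_h: float = 80.0
    snapshot_min: float = 90.0
    step_minutes: float = 30.0
    seed: int = 0

    def table_row(self):
        r = self.rules
        return (r.dz_exit.name, r.ez_exit.name, r.division.name, r.growth.name)

    def validate(self):
        expected = MODEL_TABLE[self.model_id]
        got = self.table_row()
        if got != expected:
            warnings.warn(
                f"model {self.model_id} rules {got} deviate from the "
                f"canonical row {expected}; proceeding (exploration allowed)",
                stacklevel=2,
            )
        return self


def _sizer(noise=0.25):
    return SizerDivision(
        threshold=360.0,
        threshold_by_file={f: 180.0 for f in INNER_FILES},
        noise=noise,
    )


def model_config(model_id, **overrides):
    """Canonical configuration for one of the twelve models.

    Keyword overrides replace top-level fields after construction;
    overrides that contradict the canonical rule set are accepted with
    a warning so parameter exploration stays possible.
    """
    if model_id not in MODEL_TABLE:
        raise ValueError(f"unknown model id {model_id!r} (expected 1..12)")
    growth_lin = RelativeGrowth(rate_dz=0.023, rate_ez=0.1)
    cfg = ModelConfig(model_id=model_id)
    if model_id == 1:
        cfg.rules = RuleConfig(
            division=TimerDivision(cct=CCT),
            dz_exit=CounterExit(3),
            ez_exit=TimerExit(4440.0),
            growth=ConstantIncrement(4.0),
        )
    elif model_id == 2:
        cfg.rules = RuleConfig(
            division=TimerDivision(cct=CCT),
            dz_exit=TimerExit(4 * CCT),
            ez_exit=TimerExit(4 * CCT + 420.0),
            growth=growth_lin,
        )
    elif model_id == 3:
        cfg.rules = RuleConfig(
            division=TimerDivision(cct=CCT),
            dz_exit=CounterExit(3),
            ez_exit=TimerExit(4440.0),
            growth=growth_lin,
        )
    elif model_id == 4:
        cfg.rules = RuleConfig(
            division=TimerDivision(cct=CCT, noise=0.25, first_noise=0.10),
            dz_exit=TimerExit(4 * CCT),
            ez_exit=TimerExit(4 * CCT + 420.0),
            growth=growth_lin,
        )
    elif model_id == 5:
        cfg.rules = RuleConfig(
            division=TimerDivision(
                cct=CCT,
                cct_by_file={f: 1080.0 for f in INNER_FILES},
                noise=0.10,
            ),
            dz_exit=CounterExit(3),
            ez_exit=TimerExit(4440.0),
            growth=replace(growth_lin, rate_ez=0.03),
        )
    elif model_id == 6:
        cfg.rules = RuleConfig(
            division=SizerDivision(threshold=360.0, noise=0.10),
            dz_exit=CounterExit(3),
            ez_exit=TimerExit(4440.0),
            growth=growth_lin,
        )
    elif model_id == 7:
        cfg.rules = RuleConfig(
            division=_sizer(noise=0.10),
            dz_exit=CounterExit(3),
            ez_exit=TimerExit(4440.0),
            growth=growth_lin,
        )
    elif model_id in (8, 9):
        cfg.grid_kind = "developed"
        cfg.rules = RuleConfig(
            division=_sizer(),
            dz_exit=RulerExit(240.0),
            ez_exit=RulerExit(750.0),
            growth=RelativeGrowth(rate_dz=0.02, rate_ez=0.2),
        )
        if model_id == 9:
            cfg.transport = TransportParams(
                boundary_flux=2e7, k_prod_area=100.0, k_deg=3e-4
            )
            cfg.pin_scheme = "reverse_fountain"
            cfg.species = ("auxin",)
            cfg.source_mode = "MIXED"
            cfg.chem_burnin_min = 240.0
    elif model_id == 10:
        cfg.grid_kind = "developed"
        cfg.rules = RuleConfig(
            division=_sizer(),
            dz_exit=AuxinThresholdExit(upper=13.5, lower=8.8),
            ez_exit=AuxinThresholdExit(upper=13.5, lower=8.8),
            growth=RelativeGrowth(rate_dz=0.02, rate_ez=0.2),
        )
        cfg.transport = TransportParams(boundary_flux=2e7, k_deg=3e-4)
        cfg.pin_scheme = "reverse_fountain"
        cfg.species = ("auxin",)
        cfg.source_mode = "EXTERNAL"
        cfg.chem_burnin_min = 240.0
    elif model_id == 11:
        thr = AuxinThresholdExit(
            upper=13.5, lower=8.8,
            upper_by_file={f: 40.5 for f in INNER_FILES},
            lower_by_file={f: 26.4 for f in INNER_FILES},
        )
        cfg.grid_kind = "developed"
        cfg.rules = RuleConfig(
            division=_sizer(),
            dz_exit=thr,
            ez_exit=thr,
            growth=LayerDrivenGrowth(
                driver_files=(1, 10),
                inner=RelativeGrowth(rate_dz=0.02, rate_ez=0.2),
            ),
        )
        cfg.transport = TransportParams(boundary_flux=2e7, k_deg=3e-4)
        cfg.pin_scheme = "reverse_fountain"
        cfg.species = ("auxin",)
        cfg.source_mode = "EXTERNAL"
        cfg.chem_burnin_min = 240.0
    elif model_id == 12:
        cfg.grid_kind = "developed"
        cfg.rules = RuleConfig(
            division=_sizer(),
            dz_exit=Shy2ThresholdExit(threshold=3.0),
            ez_exit=GaThresholdExit(min_conc=1.0),
            growth=RelativeGrowth(rate_dz=0.02, rate_ez=0.2),
        )
        cfg.transport = TransportParams(
            diffusion=300.0, k_import=100.0, k_export=1200.0, k_deg=0.1,
            boundary_flux=0.0, k_prod_area=0.0, k_prod_qc=2e3,
            ck_diffusion=100.0, ck_source=0.0, ck_prod_area=0.5,
            ck_K_aux=10.0, ck_deg=0.02,
            shy2_prod=0.03, shy2_K_ck=10.0,
            shy2_deg0=3e-3, shy2_deg_aux=8e-3, shy2_K_aux=20.0,
            pin_K=2.5, pin_hill=6.0,
            ga_prod_per_width=0.05, dt_chem=2.0,
        )
        cfg.pin_scheme = "reverse_fountain"
        cfg.pin_density = 4.0
        cfg.species = ("auxin", "cytokinin", "shy2", "ga")
        cfg.source_mode = "PROD_AREA"
        cfg.chem_burnin_min = 1200.0
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    return cfg.validate()


# ------------------------------------------------------------------ driver


@dataclass
class Trajectory:
    times: list
    frames: list                      # per-snapshot DataFrames
    events: pd.DataFrame
    parent_map: dict                  # parent cell id -> (daughter ids)
    final_mesh: Mesh
    config: ModelConfig = None
    meshes: list = None

    def root_length_series(self):
        times = np.array(self.times)
        lengths = np.array([
            f.loc[f["role"] == "BODY", "pos_max"].max() for f in self.frames
        ])
        return times, lengths

    def long_frame(self):
        return pd.concat(self.frames, ignore_index=True)


def dz_extent(frame, window=9):
    """Axial extent of the division-competent zone (µm from the QC face).

    The boundary is where the rolling majority of cells (ordered by
    axial position) stops being STEM/DZ, which is robust against single
    straggler cells advected shootward before transitioning.
    """
    body = frame[frame["role"] == "BODY"].sort_values("position")
    if body.empty:
        return 0.0
    is_dz = body["zone"].isin(["STEM", "DZ"]).to_numpy().astype(float)
    pos = body["position"].to_numpy()
    frac = pd.Series(is_dz).rolling(window, center=True, min_periods=1).mean()
    below = np.nonzero(frac.to_numpy() < 0.5)[0]
    if below.size == 0:
        return float(max(0.0, pos.max()))     # whole root still meristematic
    return float(max(0.0, pos[below[0]]))


def _refresh_stemness(mesh):
    """Re-pin stem identity right after divisions; newly released cells
    start their clocks and counters at zero."""
    contact = mesh.qc_contact_cells()
    for cid, cell in mesh.cells.items():
        if cell.role is Role.COLUMELLA_QC:
            continue
        if cid in contact:
            cell.zone = Zone.STEM
            cell.t_release = 0.0
            cell.division_count = 0
        elif cell.zone is Zone.STEM:
            cell.zone = Zone.DZ
            cell.t_release = 0.0
            cell.division_count = 0


def run_model(config, rng=None, keep_meshes=False):
    """Run one model configuration; deterministic given the seed.

    Raises :class:`DegenerationError` (with the partial trajectory
    attached) when the mesh self-intersects or a cell collapses -- for
    rule sets that violate uniform strain this outcome is itself the
    result.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    widths = config.column_widths
    if widths is None:
        widths = standard_column_widths(config.n_columns)
    if config.grid_kind == "developed":
        mesh = build_developed_grid(config.n_columns, widths,
                                    body_length=config.body_length,
                                    qc_row_height=config.row_height, rng=rng)
    else:
        mesh = build_root_grid(config.n_columns, config.n_rows, widths,
                               config.row_height)
    layout = None
    if config.species:
        for cell in mesh.cells.values():
            for sp in config.species:
                cell.chem.setdefault(sp, 0.0)
        layout = assign_pin_layout(mesh, config.pin_scheme, config.pin_density)
        if config.chem_burnin_min > 0:
            step_chemistry(mesh, config.transport, layout,
                           dt=config.chem_burnin_min, mode=config.source_mode,
                           species=config.species)
    _refresh_stemness(mesh)
    for cell in mesh.cells.values():
        if cell.role is Role.BODY:
            resample_noise(cell, config.rules.division, rng)

    dt = config.step_minutes
    n_steps = int(round(config.duration_h * 60.0 / dt))
    events = []
    parent_map = {}
    times = [mesh.time]
    frames = [snapshot_frame(mesh)]
    meshes = [mesh.copy()] if keep_meshes else None
    last_snapshot = mesh.time
    driver_files = (
        config.rules.growth.driver_files
        if isinstance(config.rules.growth, LayerDrivenGrowth) else None
    )

    def _finish():
        return Trajectory(times, frames, pd.DataFrame(
            events, columns=["time", "event", "cell_id", "detail"]),
            parent_map, mesh, config, meshes)

    for k in range(n_steps):
        t_next = mesh.time + dt
        update_clocks(mesh, dt)
        for cid in list(mesh.cells):
            cell = mesh.cells[cid]
            if cell.role is not Role.BODY or cell.zone is Zone.STEM:
                continue
            before = cell.zone
            after = zone_transition(cell, mesh, config.rules)
            if after is not before:
                events.append((t_next, "transition", cid,
                               f"{before.name}->{after.name}"))
        for cell in mesh.cells.values():
            reg.apply_growth(cell, mesh, config.rules.growth, dt,
                             config.step_minutes)
        if config.species:
            step_chemistry(mesh, config.transport, layout, dt=dt,
                           mode=config.source_mode, species=config.species)
        divided = True
        guard = 0
        while divided and guard < 4:   # daughters may immediately re-qualify
            divided = False
            guard += 1
            for cid in sorted(mesh.cells):
                cell = mesh.cells.get(cid)
                if cell is None or cell.role is not Role.BODY:
                    continue
                if cell.zone not in (Zone.STEM, Zone.DZ):
                    continue
                if should_divide(cell, mesh, config.rules.division, rng):
                    d1, d2 = divide_cell_horizontal(mesh, cell)
                    parent_map[cid] = (d1.id, d2.id)
                    for d in (d1, d2):
                        resample_noise(d, config.rules.division, rng)
                    events.append((t_next, "division", cid,
                                   f"{d1.id}+{d2.id}"))
                    divided = True
            if divided:
                _refresh_stemness(mesh)
        relax(mesh, config.mech, rng)
        if driver_files is not None:
            layer_driven_follow(mesh, driver_files)
        if config.species and config.pin_scheme != "apolar":
            layout = assign_pin_layout(mesh, config.pin_scheme,
                                       config.pin_density)
        mesh.time = t_next
        try:
            if k % 5 == 4 or k == n_steps - 1:
                mesh.check_planarity()
        except DegenerationError as exc:
            times.append(mesh.time)
            frames.append(snapshot_frame(mesh))
            if keep_meshes:
                meshes.append(mesh.copy())
            raise DegenerationError(str(exc), trajectory=_finish()) from None
        if mesh.time - last_snapshot >= config.snapshot_min - 1e-9 \
                or k == n_steps - 1:
            last_snapshot = mesh.time
            times.append(mesh.time)
            frames.append(snapshot_frame(mesh))
            if keep_meshes:
                meshes.append(mesh.copy())
    return _finish()


def perturbation_experiment(config, factor_auxin=4.0, factor_cytokinin=4.0,
                            rng=None):
    """Hormone-source perturbations of the cross-talk model.

    Runs the reference configuration plus variants with the external
    auxin and cytokinin sources scaled, and reports the axial extent of
    the division zone in the final snapshot of each run.
    """
    if config.model_id != 12:
        raise ValueError("perturbation experiment is defined for model 12")
    out = {}
    for name, (fa, fc) in (
        ("reference", (1.0, 1.0)),
        ("auxin", (factor_auxin, 1.0)),
        ("cytokinin", (1.0, factor_cytokinin)),
    ):
        tp = replace(
            config.transport,
            boundary_flux=config.transport.boundary_flux * fa,
            k_prod_qc=config.transport.k_prod_qc * fa,
            ck_source=config.transport.ck_source * fc,
            ck_prod_area=config.transport.ck_prod_area * fc,
        )
        cfg = replace(config, transport=tp)
        traj = run_model(cfg, rng=np.random.default_rng(config.seed)
                         if rng is None else rng)
        out[name] = dz_extent(traj.frames[-1])
    return out


# ------------------------------------------------------- config (de)serialize


def config_to_text(cfg):
    """Serialize a ModelConfig as sectioned key/value text (JSON values)."""
    def rule_dict(rule):
        d = asdict(rule)
        d["_rule"] = type(rule).__name__
        if "inner" in d and hasattr(rule, "inner"):
            d["inner"] = asdict(rule.inner)
            d["inner"]["_rule"] = type(rule.inner).__name__
        return d

    sections = {
        "model": {
            "model_id": cfg.model_id, "duration_h": cfg.duration_h,
            "snapshot_min": cfg.snapshot_min, "step_minutes": cfg.step_minutes,
            "seed": cfg.seed, "source_mode": cfg.source_mode,
            "species": list(cfg.species), "pin_scheme": cfg.pin_scheme,
            "pin_density": cfg.pin_density,
            "chem_burnin_min": cfg.chem_burnin_min,
        },
        "grid": {
            "n_columns": cfg.n_columns, "n_rows": cfg.n_rows,
            "column_widths": cfg.column_widths, "row_height": cfg.row_height,
        },
        "mechanics": asdict(cfg.mech),
        "transport": asdict(cfg.transport) if cfg.transport else None,
        "rules": {
            "division": rule_dict(cfg.rules.division),
            "dz_exit": rule_dict(cfg.rules.dz_exit),
            "ez_exit": rule_dict(cfg.rules.ez_exit),
            "growth": rule_dict(cfg.rules.growth),
            "step_minutes": cfg.rules.step_minutes,
        },
    }
    lines = []
    for name, body in sections.items():
        lines.append(f"[{name}]")
        if body is None:
            lines.append("none = true")
        else:
            for key, val in body.items():
                lines.append(f"{key} = {json.dumps(val)}")
        lines.append("")
    return "\n".join(lines)


_RULE_TYPES = {
    c.__name__: c for c in (
        TimerDivision, SizerDivision, CounterExit, TimerExit, RulerExit,
        AuxinThresholdExit, Shy2ThresholdExit, GaThresholdExit,
        ConstantIncrement, RelativeGrowth, LayerDrivenGrowth,
    )
}


def _rule_from_dict(d):
    d = dict(d)
    cls = _RULE_TYPES[d.pop("_rule")]
    if "inner" in d and isinstance(d["inner"], dict):
        d["inner"] = _rule_from_dict(d["inner"])
    for key in ("cct_by_file", "threshold_by_file", "upper_by_file",
                "lower_by_file"):
        if d.get(key):
            d[key] = {int(k): v for k, v in d[key].items()}
    if "driver_files" in d and d["driver_files"] is not None:
        d["driver_files"] = tuple(d["driver_files"])
    return cls(**d)


def config_from_text(text):
    sections = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
            continue
        key, _, val = line.partition("=")
        sections[current][key.strip()] = json.loads(val.strip())
    model = sections["model"]
    rules_sec = sections["rules"]
    transport_sec = sections.get("transport", {})
    transport = (
        None if transport_sec.get("none")
        else TransportParams(**transport_sec)
    )
    cfg = ModelConfig(
        model_id=model["model_id"],
        n_columns=sections["grid"]["n_columns"],
        n_rows=sections["grid"]["n_rows"],
        column_widths=sections["grid"]["column_widths"],
        row_height=sections["grid"]["row_height"],
        mech=MechParams(**sections["mechanics"]),
        rules=RuleConfig(
            division=_rule_from_dict(rules_sec["division"]),
            dz_exit=_rule_from_dict(rules_sec["dz_exit"]),
            ez_exit=_rule_from_dict(rules_sec["ez_exit"]),
            growth=_rule_from_dict(rules_sec["growth"]),
            step_minutes=rules_sec["step_minutes"],
        ),
        transport=transport,
        pin_scheme=model["pin_scheme"],
        pin_density=model["pin_density"],
        source_mode=model["source_mode"],
        species=tuple(model["species"]),
        chem_burnin_min=model["chem_burnin_min"],
        duration_h=model["duration_h"],
        snapshot_min=model["snapshot_min"],
        step_minutes=model["step_minutes"],
        seed=model["seed"],
    )
    return cfg.validate()
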