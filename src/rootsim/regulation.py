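"""Developmental rule library: clocks, division decisions, zone
transitions and growth-rate assignment.

Cells in wall contact with the columella/QC block behave as stem cells:
their release clock and division counter are pinned to zero and they
divide at the pre-set frequency.  Once a division separates a daughter
from the QC block, the daughter's clock starts running and the cell
becomes a typical meristematic (DZ) cell.  All downstream decisions --
when to stop dividing, when to start accelerated elongation, when to
mature -- are taken by exchangeable rules:

* timers (fixed duration since QC release),
* counters (fixed number of divisions since release),
* sizers (division at a critical area, optionally per cell file),
* rulers (fixed axial distance from the QC face), and
* morphogen thresholds (auxin two-threshold scheme, SHY2 and GA
  concentration thresholds).

Zone transitions are one-way: STEM -> DZ -> EZ -> MZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_mesh import Mesh, Role, Zone


# ------------------------------------------------------------------- rules


@dataclass
class TimerDivision:
    """Divide when the time since the last division reaches the cell
    cycle time (CCT), optionally layer-specific, with uniform
    multiplicative noise resampled once per cycle."""

    cct: float = 900.0                      # min
    cct_by_file: dict = None                # file_index -> CCT override
    noise: float = 0.0                      # max fractional noise per cycle
    first_noise: float = None               # override for the first division

    def cct_for(self, cell):
        if self.cct_by_file and cell.file_index in self.cct_by_file:
            return self.cct_by_file[cell.file_index]
        return self.cct

    name = "timer"


@dataclass
class SizerDivision:
    """Divide on reaching a critical area, optionally per file."""

    threshold: float = 360.0                # µm²
    threshold_by_file: dict = None
    noise: float = 0.0
    first_noise: float = None

    def threshold_for(self, cell):
        if self.threshold_by_file and cell.file_index in self.threshold_by_file:
            return self.threshold_by_file[cell.file_index]
        return self.threshold

    name = "sizer"


@dataclass
class CounterExit:
    n_divisions: int = 3
    name = "counter"


@dataclass
class TimerExit:
    duration: float = 3600.0                # min since QC release
    name = "timer"


@dataclass
class RulerExit:
    distance: float = 240.0                 # µm from the QC face
    name = "ruler"


@dataclass
class AuxinThresholdExit:
    """Two-threshold auxin readout: divide and grow slowly above the
    upper threshold, accelerate between the two, mature below the lower.
    Per-file thresholds implement layer-specific sensing."""

    upper: float = 13.5                     # AU
    lower: float = 8.8                      # AU
    upper_by_file: dict = None
    lower_by_file: dict = None

    def upper_for(self, cell):
        if self.upper_by_file and cell.file_index in self.upper_by_file:
            return self.upper_by_file[cell.file_index]
        return self.upper

    def lower_for(self, cell):
        if self.lower_by_file and cell.file_index in self.lower_by_file:
            return self.lower_by_file[cell.file_index]
        return self.lower

    name = "auxin_threshold"


@dataclass
class Shy2ThresholdExit:
    threshold: float = 1.0                  # AU
    name = "shy2_threshold"


@dataclass
class GaThresholdExit:
    min_conc: float = 0.1                   # AU; mature below this
    name = "ga_threshold"


@dataclass
class ConstantIncrement:
    """Absolute growth: the same target-area increment for every cell
    regardless of size (violates uniform relative strain whenever file
    widths differ)."""

    increment: float = 20.0                 # µm² per simulation step
    name = "constant"


@dataclass
class RelativeGrowth:
    """Relative (exponential) growth with a zone-specific rate; the
    elongation zone accelerates ten-fold by default."""

    rate_dz: float = 0.02                   # fraction per simulation step
    rate_ez: float = 0.2

    def rate_for(self, zone):
        if zone in (Zone.STEM, Zone.DZ):
            return self.rate_dz
        if zone is Zone.EZ:
            return self.rate_ez
        return 0.0

    name = "linear"


@dataclass
class LayerDrivenGrowth:
    """Driver files grow by their own rule; all other body cells follow
    passively (target reset to actual each step)."""

    driver_files: tuple = (1, 10)
    inner: RelativeGrowth = field(default_factory=RelativeGrowth)
    name = "layer_driven"


@dataclass
class RuleConfig:
    division: object = field(default_factory=TimerDivision)
    dz_exit: object = field(default_factory=TimerExit)
    ez_exit: object = field(default_factory=lambda: TimerExit(3900.0))
    growth: object = field(default_factory=RelativeGrowth)
    step_minutes: float = 30.0


# -------------------------------------------------------------- operations


def update_clocks(mesh, dt):
    """Advance release clocks and re-pin stem identity.

    Cells sharing a wall with the QC block get ``t_release = 0`` and
    ``division_count = 0`` (stemness); every other body cell's release
    clock and division clock advance by ``dt``.
    """
    contact = mesh.qc_contact_cells()
    for cid, cell in mesh.cells.items():
        if cell.role is Role.COLUMELLA_QC:
            continue
        if cid in contact:
            cell.t_release = 0.0
            cell.division_count = 0
            cell.zone = Zone.STEM
            cell.t_since_division += dt
        else:
            if cell.zone is Zone.STEM:
                cell.zone = Zone.DZ       # release: clock starts now
            cell.t_release += dt
            cell.t_since_division += dt
    return mesh


def resample_noise(cell, rule, rng):
    """Draw the fractional timer/sizer noise for the coming cycle."""
    noise = getattr(rule, "noise", 0.0) or 0.0
    first = getattr(rule, "first_noise", None)
    if first is not None and cell.division_count == 0:
        noise = first
    cell.noise_mult = float(rng.uniform(-noise, noise)) if noise > 0 else 0.0


def should_divide(cell, mesh, rule, rng=None):
    """Division decision for a STEM or DZ cell under the configured rule."""
    if cell.zone not in (Zone.STEM, Zone.DZ):
        return False
    if isinstance(rule, TimerDivision):
        return cell.t_since_division >= rule.cct_for(cell) * (1.0 + cell.noise_mult)
    if isinstance(rule, SizerDivision):
        area = mesh.area(cell)
        return area >= rule.threshold_for(cell) * (1.0 + cell.noise_mult)
    raise TypeError(f"unknown division rule {rule!r}")


def _conc(cell, mesh, species):
    area = mesh.area(cell)
    return cell.chem.get(species, 0.0) / area if area > 0 else 0.0


def zone_transition(cell, mesh, rules):
    """One-way zone update for a single cell; returns the new zone."""
    if cell.role is Role.COLUMELLA_QC or cell.zone is Zone.STEM:
        return cell.zone
    if cell.zone is Zone.DZ:
        if _dz_exits(cell, mesh, rules.dz_exit):
            cell.zone = Zone.EZ
    if cell.zone is Zone.EZ:
        if _ez_exits(cell, mesh, rules.ez_exit):
            cell.zone = Zone.MZ
    return cell.zone


def _dz_exits(cell, mesh, rule):
    if isinstance(rule, CounterExit):
        return cell.division_count >= rule.n_divisions
    if isinstance(rule, TimerExit):
        return cell.t_release >= rule.duration
    if isinstance(rule, RulerExit):
        return mesh.axial_position(cell) >= rule.distance
    if isinstance(rule, AuxinThresholdExit):
        if "auxin" not in cell.chem:
            raise ValueError("auxin-threshold rule needs an auxin field")
        return _conc(cell, mesh, "auxin") < rule.upper_for(cell)
    if isinstance(rule, Shy2ThresholdExit):
        if "shy2" not in cell.chem:
            raise ValueError("SHY2-threshold rule needs a SHY2 field")
        return _conc(cell, mesh, "shy2") >= rule.threshold
    raise TypeError(f"unknown DZ-exit rule {rule!r}")


def _ez_exits(cell, mesh, rule):
    if isinstance(rule, TimerExit):
        return cell.t_release >= rule.duration
    if isinstance(rule, RulerExit):
        return mesh.axial_position(cell) >= rule.distance
    if isinstance(rule, AuxinThresholdExit):
        return _conc(cell, mesh, "auxin") < rule.lower_for(cell)
    if isinstance(rule, GaThresholdExit):
        if "ga" not in cell.chem:
            raise ValueError("GA-threshold rule needs a GA field")
        return _conc(cell, mesh, "ga") < rule.min_conc
    raise TypeError(f"unknown EZ-exit rule {rule!r}")


def apply_growth(cell, mesh, rule, dt, step_minutes=30.0):
    """Advance the cell's target area by the configured growth law.

    Mature and columella/QC cells keep their target areas frozen.
    """
    if cell.role is Role.COLUMELLA_QC or cell.zone is Zone.MZ:
        return cell.target_area
    frac = dt / step_minutes
    if isinstance(rule, ConstantIncrement):
        cell.target_area += rule.increment * frac
    elif isinstance(rule, RelativeGrowth):
        cell.target_area *= 1.0 + rule.rate_for(cell.zone) * frac
    elif isinstance(rule, LayerDrivenGrowth):
        if cell.file_index in rule.driver_files:
            apply_growth(cell, mesh, rule.inner, dt, step_minutes)
        # followers handled by layer_driven_follow at end of step
    else:
        raise TypeError(f"unknown growth rule {rule!r}")
    return cell.target_area


def layer_driven_follow(mesh, driver_files):
    """Reset every non-driver body cell's target area to its actual
    area, so followers comply with whatever the driver files impose
    (resisting only within the current step)."""
    for cell in mesh.cells.values():
        if cell.role is Role.COLUMELLA_QC:
            continue
        if cell.file_index in driver_files:
            continue
        cell.target_area = mesh.area(cell)
    return mesh
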