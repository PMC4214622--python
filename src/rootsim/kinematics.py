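"""Kinematic analysis of simulated root growth.

Works on per-cell tabular snapshots (one row per cell per time point,
as produced by :func:`rootsim.core_mesh.snapshot_frame` or loaded from
CSV): length/velocity/strain profiles along the growth axis, kernel
smoothing, replicate binning, the uniform-strain violation score, and
steady-state detection, bundled into a three-criteria realism report.

The central diagnostic is the uniform longitudinal strain rule (ULSR):
in a unidirectionally, symplastically growing root all points at the
same axial position must share the same relative elongation rate;
persistent differences inevitably distort the tissue.  The violation
score measures, over a persistence window, the mean spread (max - min)
of per-cell relative elongation rates among cells straddling each
sampled axial position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPIDERMAL = "EPIDERMAL"
ALL = "ALL"


def areal_strain_rate(area_prev, area_now):
    """Relative area change between consecutive snapshots of one cell."""
    if area_prev <= 0:
        raise ValueError("previous area must be positive")
    return (area_now - area_prev) / area_prev


def growth_potential(area, target_area):
    """A / A_T; below one the cell is pushing to expand ('turgor')."""
    if target_area <= 0:
        raise ValueError("target area must be positive")
    return area / target_area


def _filter_layer(frame, layer_filter):
    frame = frame[frame["role"] == "BODY"]
    if layer_filter == ALL:
        return frame
    if layer_filter == EPIDERMAL:
        files = frame["file_index"]
        return frame[(files == files.min()) | (files == files.max())]
    raise ValueError(f"unknown layer filter {layer_filter!r}")


@dataclass
class KinematicProfile:
    positions: np.ndarray           # µm from the QC face, increasing
    values: np.ndarray
    quantity: str = ""
    smoothing: str = "none"
    bandwidth: float = None
    replicates: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) < 0):
            order = np.argsort(self.positions)
            self.positions = self.positions[order]
            self.values = self.values[order]


def length_profile(frame, layer_filter=ALL):
    """Cell axial length against centroid position for one snapshot."""
    sel = _filter_layer(frame, layer_filter)
    sel = sel.sort_values("position")
    return KinematicProfile(
        sel["position"].to_numpy(), sel["length"].to_numpy(),
        quantity="cell length",
    )


def smooth_profile(positions, values, bandwidth=40.0, grid_interval=10.0,
                   grid=None):
    """Local-linear Gaussian-kernel regression on a regular grid.

    The estimator solves a weighted straight-line fit around every grid
    point, so constants and exact lines are reproduced; the grid spacing
    follows the 5-25 µm interpolation convention of kinematic studies.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to smooth")
    if grid is None:
        grid = np.arange(x.min(), x.max() + 0.5 * grid_interval, grid_interval)
    fitted = np.empty(grid.shape)
    for k, g in enumerate(grid):
        u = (x - g) / bandwidth
        w = np.exp(-0.5 * u * u)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 1e-12 else 0.0
        fitted[k] = ym + slope * (g - xm)
    return KinematicProfile(grid, fitted, smoothing="local-linear",
                            bandwidth=bandwidth)


def _match_cells(frame0, frame1, parent_map=None):
    """Pair cells across two snapshots, summing daughters over divisions.

    Returns arrays (position at t0, length at t0, length at t1).
    Lineages are followed through ``parent_map`` (parent id ->
    (daughter, daughter)); a parent's interval at t1 is reconstructed as
    the union of its daughters' axial spans.
    """
    f1 = frame1.set_index("cell_id")
    rows = []
    for _, row in frame0[frame0["role"] == "BODY"].iterrows():
        cid = row["cell_id"]
        leaves = _leaves(cid, set(f1.index), parent_map or {})
        if not leaves:
            continue
        lo = min(f1.loc[l, "pos_min"] for l in leaves)
        hi = max(f1.loc[l, "pos_max"] for l in leaves)
        rows.append((row["position"], row["pos_min"], row["pos_max"],
                     row["length"], hi - lo,
                     np.mean([f1.loc[l, "position"] for l in leaves])))
    return pd.DataFrame(
        rows, columns=["position", "pos_min", "pos_max",
                       "length0", "length1", "position1"]
    )


def _leaves(cid, present, parent_map):
    if cid in present:
        return [cid]
    if cid in parent_map:
        out = []
        for d in parent_map[cid]:
            out.extend(_leaves(d, present, parent_map))
        return out
    return []


def velocity_profile(frame0, frame1, parent_map=None):
    """Axial displacement rate of cells between two snapshots (µm/h),
    plotted against position at the first time."""
    t0 = frame0["time"].iloc[0]
    t1 = frame1["time"].iloc[0]
    if t1 <= t0:
        raise ValueError("second snapshot must be later than the first")
    dt_h = (t1 - t0) / 60.0
    m = _match_cells(frame0, frame1, parent_map)
    vel = (m["position1"] - m["position"]) / dt_h
    order = np.argsort(m["position"].to_numpy())
    return KinematicProfile(
        m["position"].to_numpy()[order], vel.to_numpy()[order],
        quantity="velocity (µm/h)",
    )


def bin_average(profiles, bin_width=25.0):
    """Pool replicate profiles into fixed axial bins (mean ± sd).

    Empty bins are absent from the output rather than reported as zero.
    """
    xs = np.concatenate([p.positions for p in profiles])
    ys = np.concatenate([p.values for p in profiles])
    idx = np.floor(xs / bin_width).astype(int)
    rows = []
    for b in sorted(set(idx)):
        sel = ys[idx == b]
        rows.append({
            "position": (b + 0.5) * bin_width,
            "mean": float(sel.mean()),
            "sd": float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
            "n": int(sel.size),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- ULSR


@dataclass
class UlsrReport:
    score: float                    # mean strain-rate spread, per hour
    threshold: float
    window_min: float
    positions: np.ndarray = None
    spread: np.ndarray = None       # time-averaged spread per position

    @property
    def verdict(self):
        """True when the trajectory conforms to uniform strain."""
        return self.score < self.threshold


def ulsr_violation(trajectory, window_min=300.0, n_axial=25,
                   threshold=0.02, parent_map=None):
    """Uniform-strain violation score over the trailing time window.

    For every pair of consecutive snapshots inside the window the
    relative longitudinal elongation rate of each cell (per hour,
    daughters merged across divisions) is attributed to every sampled
    axial position its span covers; the spread is max - min where at
    least two cells overlap.  The score is the time-average of the mean
    spread; zero if and only if strain is uniform wherever comparable.
    """
    frames, parent_map = _traj_frames(trajectory, parent_map)
    times = [f["time"].iloc[0] for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two snapshots")
    t_end = times[-1]
    use = [i for i, t in enumerate(times) if t >= t_end - window_min - 1e-9]
    if len(use) < 2:
        raise ValueError("window exceeds trajectory span")
    spreads = []
    grid = None
    for i0, i1 in zip(use[:-1], use[1:]):
        f0, f1 = frames[i0], frames[i1]
        dt_h = (times[i1] - times[i0]) / 60.0
        m = _match_cells(f0, f1, parent_map)
        m = m[m["length0"] > 0]
        rates = ((m["length1"] - m["length0"]) / m["length0"] / dt_h).to_numpy()
        lo = m["pos_min"].to_numpy()
        hi = m["pos_max"].to_numpy()
        body = f0[f0["role"] == "BODY"]
        if grid is None:
            grid = np.linspace(
                max(0.0, body["pos_min"].min()), body["pos_max"].max(), n_axial
            )
        row = np.full(grid.shape, np.nan)
        for k, p in enumerate(grid):
            cover = (lo <= p) & (hi >= p)
            if cover.sum() >= 2:
                row[k] = rates[cover].max() - rates[cover].min()
        spreads.append(row)
    spread = np.nanmean(np.vstack(spreads), axis=0)
    score = float(np.nanmean(spread)) if np.any(np.isfinite(spread)) else 0.0
    return UlsrReport(score=score, threshold=threshold,
                      window_min=window_min, positions=grid, spread=spread)


def _traj_frames(trajectory, parent_map):
    """Accept a Trajectory object, a list of frames, or a long frame."""
    if hasattr(trajectory, "frames"):
        return list(trajectory.frames), parent_map or getattr(
            trajectory, "parent_map", None
        )
    if isinstance(trajectory, pd.DataFrame):
        return (
            [g for _, g in trajectory.groupby("time", sort=True)],
            parent_map,
        )
    return list(trajectory), parent_map


# ----------------------------------------------------- steady state, realism


def steady_state_time(times, lengths, rel_tol=0.05, min_points=10):
    """Earliest time from which the organ elongation rate stays within
    ``rel_tol`` of its terminal value (linear-growth detection);
    returns None when growth never settles."""
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if times.size < min_points:
        raise ValueError(f"need at least {min_points} time points")
    slopes = np.diff(lengths) / np.diff(times)
    terminal = np.mean(slopes[-3:])
    scale = max(abs(terminal), 1e-12)
    ok = np.abs(slopes - terminal) <= rel_tol * scale
    if not ok[-1]:
        return None
    idx = len(ok)
    while idx > 0 and ok[idx - 1]:
        idx -= 1
    if idx == len(ok):
        return None
    return float(times[idx])


def size_range_profile(frame, window=50.0, step=10.0, layer_filter=EPIDERMAL,
                       min_cells=4, bandwidth=40.0):
    """Per-position max/min cell-length ratio along the growth axis.

    Measures the spread of the scatter band, not the axial trend: cell
    lengths are first normalized by the smoothed length profile (so the
    steep growth gradient of the elongation zone does not masquerade as
    per-position spread), the windowed max/min of the normalized lengths
    form upper and lower envelopes, and the reported ratio is the ratio
    of the kernel-smoothed envelopes.  Positions whose ±window/2
    interval holds fewer than ``min_cells`` cells are omitted (missing,
    not zero).  Under sizer-controlled division the expected value is
    the two-fold division span.
    """
    sel = _filter_layer(frame, layer_filter).sort_values("position")
    pos = sel["position"].to_numpy()
    length = sel["length"].to_numpy()
    if pos.size < max(min_cells, 5):
        return pd.DataFrame(columns=["position", "ratio", "n"])
    trend = smooth_profile(pos, length, bandwidth=bandwidth,
                           grid_interval=step / 2)
    norm = length / np.maximum(
        np.interp(pos, trend.positions, trend.values), 1e-9
    )
    grid = np.arange(max(0.0, pos.min()), pos.max() + step / 2, step)
    kept, hi, lo, counts = [], [], [], []
    for p in grid:
        inside = np.abs(pos - p) <= window / 2
        if inside.sum() < min_cells:
            continue
        kept.append(p)
        hi.append(norm[inside].max())
        lo.append(norm[inside].min())
        counts.append(int(inside.sum()))
    if len(kept) < 5:
        return pd.DataFrame(columns=["position", "ratio", "n"])
    kept = np.array(kept)
    hi_s = smooth_profile(kept, np.array(hi), bandwidth=bandwidth, grid=kept)
    lo_s = smooth_profile(kept, np.array(lo), bandwidth=bandwidth, grid=kept)
    ratio = hi_s.values / np.maximum(lo_s.values, 1e-9)
    return pd.DataFrame({"position": kept, "ratio": ratio, "n": counts})


def wall_skew(mesh):
    """Mean tilt |Δy|/len of horizontally oriented walls -- a distortion
    measure that stays near zero for undistorted grids."""
    num = den = 0.0
    for e in mesh.edges():
        if not e.vertical and e.length > 0:
            na, nb = mesh.nodes[e.a], mesh.nodes[e.b]
            num += abs(nb.y - na.y) / e.length
            den += 1.0
    return num / den if den else 0.0


def realism_report(trajectory, ratio_band=(1.6, 2.4), ratio_fraction=0.8,
                   ulsr_threshold=0.02, ulsr_window=300.0, rel_tol=0.05):
    """Judge a trajectory against the three realism criteria.

    (i) organ growth reaches a steady state; (ii) the cell length
    profile rises smoothly and epidermal lengths span roughly a two-fold
    range at each position; (iii) the uniform longitudinal strain rule
    is respected (violation score below threshold).
    """
    frames, parent_map = _traj_frames(trajectory, None)
    times = np.array([f["time"].iloc[0] for f in frames])
    lengths = np.array([
        f.loc[f["role"] == "BODY", "pos_max"].max() for f in frames
    ])
    try:
        t_steady = steady_state_time(times, lengths, rel_tol=rel_tol)
    except ValueError:
        t_steady = None
    final = frames[-1]
    ratios = size_range_profile(final)
    in_band = (
        float(((ratios["ratio"] >= ratio_band[0])
               & (ratios["ratio"] <= ratio_band[1])).mean())
        if len(ratios) else 0.0
    )
    prof = length_profile(final, EPIDERMAL)
    smooth_ok = False
    if prof.positions.size >= 5:
        sm = smooth_profile(prof.positions, prof.values)
        drops = np.diff(sm.values)
        smooth_ok = bool(
            np.all(drops >= -0.1 * max(1e-9, sm.values.max() - sm.values.min()))
        )
    ulsr = ulsr_violation(frames, window_min=ulsr_window,
                          threshold=ulsr_threshold, parent_map=parent_map)
    return {
        "steady_state": t_steady is not None,
        "steady_state_time_h": None if t_steady is None else t_steady / 60.0,
        "two_fold_fraction": in_band,
        "two_fold_ok": in_band >= ratio_fraction,
        "smooth_profile_ok": smooth_ok,
        "ulsr_score_per_h": ulsr.score,
        "ulsr_ok": ulsr.verdict,
        "all_ok": bool(
            t_steady is not None and in_band >= ratio_fraction
            and smooth_ok and ulsr.verdict
        ),
    }
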