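"""Pressure-scan orchestration: σ_Z, equilibration windows, transition
detection, hysteresis and rupture bookkeeping.

A scan is an ordered set of lateral pressures per branch (compression,
decompression, stretching, relaxation), each with a trajectory.  Per
pressure the pipeline computes the projected and 3D area per lipid,
the headgroup Z variance σ_Z, the nematic order and director
separation, and optionally runs the rupture detector; per branch it
locates a phase transition as a single outlying jump in a chosen
metric; between paired branches it reports the hysteresis shift of the
transition midpoint.

σ_Z is reported as a *variance* (nm²) of the phosphorus Z coordinates
per leaflet, leaflet-averaged then frame-averaged; the standard
deviation is available behind a flag since the notation σ is also used
for that quantity.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .area import apl3d, apl_series, projected_apl
from .frames import BoxedFrame, LipidTopology, Trajectory
from .geometry import TOP, BOTTOM, LeafletAssignment, assign_leaflets
from .order import order_series
from .profiles import RuptureReport, detect_rupture


def sigma_z(traj: Trajectory | Sequence[BoxedFrame], topology: LipidTopology,
            assignment: LeafletAssignment | None = None,
            window: tuple[float, float] | None = None,
            as_std: bool = False) -> float:
    """Headgroup-P Z variance (nm²), leaflet- then frame-averaged.

    ``as_std=True`` returns the square root (nm) instead.
    """
    frames = [f for f in traj
              if window is None or window[0] <= f.time <= window[1]]
    if not frames:
        raise ValueError("window contains no frames")
    vals = []
    for f in frames:
        asg = assignment or assign_leaflets(f, topology)
        per_leaf = []
        for leaf in (TOP, BOTTOM):
            idx = asg.indices(leaf)
            if len(idx) == 0:
                raise ValueError(f"empty leaflet {leaf!r}")
            z = f.positions[topology.p_indices[idx], 2]
            per_leaf.append(np.var(z))
        vals.append(np.mean(per_leaf))
    out = float(np.mean(vals))
    return math.sqrt(out) if as_std else out


def equilibration_window(times: np.ndarray, values: np.ndarray | None = None,
                         mode: str = "fixed", discard: float = 0.0,
                         tolerance: float = 0.0) -> tuple[float, float]:
    """Analysis time range after equilibration.

    ``fixed``: drop the first ``discard`` ns.  ``auto``: the earliest
    start time from which the reverse cumulative mean of ``values``
    varies by less than ``tolerance`` over the remaining span.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ValueError("empty series")
    t_end = float(times[-1])
    if mode == "fixed":
        if t_end <= discard:
            raise ValueError(f"series span {t_end} ns does not exceed the "
                             f"discard of {discard} ns")
        return (float(discard), t_end)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    if values is None:
        raise ValueError("auto mode needs the metric series")
    values = np.asarray(values, dtype=float)
    rcm = np.cumsum(values[::-1])[::-1] / np.arange(len(values), 0, -1)
    # a window needs at least two samples to assess stationarity
    for i in range(len(values) - 1):
        tail = rcm[i:]
        if tail.max() - tail.min() < tolerance:
            return (float(times[i]), t_end)
    raise ValueError(
        f"no window found: reverse cumulative mean varies by "
        f"{rcm.max() - rcm.min():.4g} > tolerance {tolerance:.4g} everywhere")


def detect_transition(pressures: Sequence[float], values: Sequence[float],
                      jump_factor: float = 5.0) -> tuple[float, float] | None:
    """Locate a single sharp jump in a metric-vs-pressure series.

    The transition is the adjacent-pressure interval of the largest
    absolute difference, iff that difference exceeds ``jump_factor``
    times the median of the other absolute differences; a smooth
    (linear) series returns None.
    """
    p = np.asarray(pressures, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(p) < 4:
        raise ValueError("need at least 4 scan points")
    dp = np.diff(p)
    if not np.allclose(dp, dp[0]):
        raise ValueError("non-uniform pressure grid")
    d = np.abs(np.diff(v))
    i = int(np.argmax(d))
    others = np.delete(d, i)
    med = float(np.median(others))
    if d[i] > jump_factor * med and d[i] > 0:
        lo, hi = sorted((float(p[i]), float(p[i + 1])))
        return (lo, hi)
    return None


@dataclass
class ScanPoint:
    pressure: float
    branch: str
    window: tuple[float, float] | None = None
    a_xy_mean: float | None = None
    a_xy_sd: float | None = None
    apl3d_mean: float | None = None
    apl3d_sd: float | None = None
    sigma_z: float | None = None
    s_mean: float | None = None
    separation_deg: float | None = None
    rupture: dict | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class BranchResult:
    name: str
    points: list[ScanPoint]
    transition_interval: tuple[float, float] | None = None
    transition_metric: str = "a_xy_mean"

    @property
    def pressures(self) -> np.ndarray:
        return np.array([pt.pressure for pt in self.points])

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(pt, name) for pt in self.points], dtype=float)


@dataclass
class HysteresisResult:
    shift_bar: float | None
    max_pointwise_deviation: float | None = None


def hysteresis_shift(forward: BranchResult, reverse: BranchResult,
                     metric: str = "a_xy_mean") -> HysteresisResult:
    """Shift (bar) between forward and reverse transition midpoints.

    If either branch shows no transition, the branches are compared
    pointwise over their overlapping pressures and the maximum absolute
    metric deviation is reported instead (the no-hysteresis case of a
    reversible branch).
    """
    pf = set(forward.pressures.tolist())
    pr = set(reverse.pressures.tolist())
    common = sorted(pf & pr)
    if not common:
        raise ValueError("branches share no pressure range")
    fi, ri = forward.transition_interval, reverse.transition_interval
    if fi is not None and ri is not None:
        shift = (fi[0] + fi[1]) / 2 - (ri[0] + ri[1]) / 2
        return HysteresisResult(shift_bar=float(shift))
    f_map = {pt.pressure: getattr(pt, metric) for pt in forward.points}
    r_map = {pt.pressure: getattr(pt, metric) for pt in reverse.points}
    dev = max(abs(f_map[p] - r_map[p]) for p in common
              if f_map[p] is not None and r_map[p] is not None)
    return HysteresisResult(shift_bar=None, max_pointwise_deviation=float(dev))


@dataclass
class ScanResult:
    branches: dict[str, BranchResult]
    hysteresis: dict[str, dict] = field(default_factory=dict)
    rupture_table: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "branches": {
                name: {
                    "points": [pt.to_dict() for pt in br.points],
                    "transition_interval_bar": br.transition_interval,
                    "transition_metric": br.transition_metric,
                }
                for name, br in self.branches.items()
            },
            "hysteresis": self.hysteresis,
            "rupture_table": self.rupture_table,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def analyze_point(traj: Trajectory, topology: LipidTopology, pressure: float,
                  branch: str, window: tuple[float, float] | None = None,
                  compute_3d: bool = True, compute_order: bool = True,
                  compute_rupture: bool = False,
                  rupture_kwargs: Mapping | None = None,
                  sigma_as_std: bool = False) -> ScanPoint:
    frames = [f for f in traj
              if window is None or window[0] <= f.time <= window[1]]
    if not frames:
        raise ValueError(f"window {window} contains no frames")
    sub = Trajectory(frames)
    asg = assign_leaflets(frames[0], topology)
    n_ref = max(asg.n_top, asg.n_bottom)
    a_xy = np.array([projected_apl(f, n_ref) for f in frames])
    pt = ScanPoint(pressure=pressure, branch=branch,
                   window=(frames[0].time, frames[-1].time),
                   a_xy_mean=float(a_xy.mean()), a_xy_sd=float(a_xy.std()))
    if compute_3d:
        vals = np.array([
            0.5 * (apl3d(f, topology, asg, TOP) + apl3d(f, topology, asg, BOTTOM))
            for f in frames])
        pt.apl3d_mean = float(vals.mean())
        pt.apl3d_sd = float(vals.std())
    pt.sigma_z = sigma_z(sub, topology, assignment=asg, as_std=sigma_as_std)
    if compute_order:
        osr = order_series(sub, topology, assignment=asg)
        pt.s_mean = float(osr.s_window)
        pt.separation_deg = float(osr.separation_window_deg)
    if compute_rupture:
        rep = detect_rupture(sub, topology, **dict(rupture_kwargs or {}))
        pt.rupture = rep.to_dict()
    return pt


def run_scan(branches: Mapping[str, Mapping[float, tuple[Trajectory, LipidTopology]]],
             *,
             transition_metric: str = "a_xy_mean",
             jump_factor: float = 5.0,
             branch_pairs: Sequence[tuple[str, str]] = (),
             replicas: Mapping[float, Sequence[tuple[Trajectory, LipidTopology]]]
             | None = None,
             windows: Mapping[float, tuple[float, float]] | None = None,
             compute_3d: bool = True,
             compute_order: bool = True,
             compute_rupture: bool = False,
             rupture_kwargs: Mapping | None = None,
             sigma_as_std: bool = False,
             provenance: Mapping | None = None) -> ScanResult:
    """Full scan: per-pressure metrics, transitions, hysteresis, ruptures.

    ``branches`` maps branch name -> {pressure -> (trajectory,
    topology)}; ``branch_pairs`` lists (forward, reverse) names to
    compare for hysteresis; ``replicas`` feeds the per-pressure rupture
    table.  A failure at one pressure is recorded on that point and the
    scan continues.
    """
    results: dict[str, BranchResult] = {}
    for name, points in branches.items():
        pts: list[ScanPoint] = []
        for p in points:  # preserve branch ordering
            traj, topo = points[p]
            try:
                pt = analyze_point(
                    traj, topo, p, name,
                    window=(windows or {}).get(p),
                    compute_3d=compute_3d, compute_order=compute_order,
                    compute_rupture=compute_rupture,
                    rupture_kwargs=rupture_kwargs, sigma_as_std=sigma_as_std)
            except Exception as exc:  # record and continue
                pt = ScanPoint(pressure=p, branch=name, error=str(exc))
            pts.append(pt)
        br = BranchResult(name=name, points=pts, transition_metric=transition_metric)
        good = [pt for pt in pts if pt.error is None]
        if len(good) >= 4:
            try:
                br.transition_interval = detect_transition(
                    [pt.pressure for pt in good],
                    [getattr(pt, transition_metric) for pt in good],
                    jump_factor=jump_factor)
            except ValueError:
                br.transition_interval = None
        results[name] = br

    hyst: dict[str, dict] = {}
    for fw, rv in branch_pairs:
        h = hysteresis_shift(results[fw], results[rv], metric=transition_metric)
        hyst[f"{fw}->{rv}"] = {"shift_bar": h.shift_bar,
                               "max_pointwise_deviation": h.max_pointwise_deviation}

    table: list[dict] = []
    if replicas:
        for p in replicas:
            for ri, (traj, topo) in enumerate(replicas[p], start=1):
                rep = detect_rupture(traj, topo, **dict(rupture_kwargs or {}))
                table.append({"pressure_bar": p, "replica": ri,
                              "ruptured": rep.ruptured,
                              "onset_time_ns": rep.onset_time})

    prov = dict(provenance or {})
    prov.update({
        "transition_metric": transition_metric,
        "jump_factor": jump_factor,
        "sigma_reported_as": "std" if sigma_as_std else "variance",
        "rupture_thresholds": dict(rupture_kwargs or {}),
    })
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return ScanResult(branches=results, hysteresis=hyst, rupture_table=table,
                      provenance=prov)
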