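"""Mass-density profiles along the bilayer normal and rupture detection.

Profiles are computed with Z re-centred on the lipid centre of mass of
each frame (drift-free), atoms wrapped periodically into one box
height, masses accumulated into fixed-width bins and normalised by bin
volume.  Densities are reported in kg/m³.

Rupture is water percolation through the hydrophobic core: the
detector estimates bulk water density from the region at least 1 nm
beyond the headgroup peaks and flags rupture at the first frame where
the core water density (|z| ≤ core half-width) exceeds a fraction of
bulk for a sustained run of frames.  The thresholds are configuration,
not physics — the underlying observation is visual (water seen to
penetrate the core) — so every report records them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .frames import BoxedFrame, LipidTopology, Trajectory

_AMU_PER_NM3_TO_KG_M3 = 1.66053906892


def _selection_indices(frame: BoxedFrame, topology: LipidTopology,
                       selection) -> np.ndarray:
    if isinstance(selection, str):
        if selection == "headgroups":
            idx = [i for l in topology.lipids for i in (l.phosphorus, l.nitrogen)]
            return np.array(idx, dtype=int)
        if selection == "phosphorus":
            return topology.p_indices
        if selection == "water":
            return np.asarray(topology.water_oxygens, dtype=int)
        selection = {selection}
    names = set(selection)
    return np.nonzero(np.isin(frame.names.astype(str), list(names)))[0]


def _center_z(frame: BoxedFrame, topology: LipidTopology) -> float:
    idx = topology.lipid_atom_indices()
    if len(idx) == 0:  # no lipids: centre on the box
        return frame.box_z / 2
    m = frame.masses[idx]
    return float(np.average(frame.positions[idx, 2], weights=m))


@dataclass
class DensityProfile:
    """Binned mass density along Z, centred on the bilayer."""

    bin_edges: np.ndarray  # nm, bilayer-centred
    density: np.ndarray  # kg/m^3 per bin
    selection: str
    window: tuple[float, float]
    box_xy_area: float  # nm^2, mean over the window

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integrated_mass(self) -> float:
        """Total selected mass (amu) implied by the profile."""
        vol = self.bin_width * self.box_xy_area  # nm^3 per bin
        return float(self.density.sum() * vol / _AMU_PER_NM3_TO_KG_M3)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"bin_center_nm": self.bin_centers,
                      f"density_{self.selection}_kg_m3": self.density,
                      }).to_csv(path, index=False)


def density_profile(traj: Trajectory | Iterable[BoxedFrame],
                    topology: LipidTopology,
                    selection="headgroups",
                    bin_width: float = 0.1,
                    window: tuple[float, float] | None = None,
                    windows: Sequence[tuple[float, float]] | None = None,
                    ):
    """Window-averaged mass-density profile(s) along Z.

    ``windows`` (a list of disjoint time ranges) returns one profile
    per range in a single pass — the time-resolved view used to watch
    an undulation or rupture develop.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    if windows is None:
        single = True
        if window is None:
            window = (frames[0].time, frames[-1].time)
        windows = [window]
    else:
        single = False
    sel0 = _selection_indices(frames[0], topology, selection)
    if len(sel0) == 0:
        raise ValueError(f"empty selection {selection!r}")

    box_z = max(f.box_z for f in frames)
    n_bins = max(10, int(np.ceil(box_z / bin_width)))
    half = n_bins * bin_width / 2
    edges = np.linspace(-half, half, n_bins + 1)

    out = []
    for w in windows:
        t0, t1 = w
        in_win = [f for f in frames if t0 <= f.time <= t1]
        if not in_win:
            raise ValueError(f"window {w} contains no frames")
        acc = np.zeros(n_bins)
        area = 0.0
        for f in in_win:
            z = f.positions[sel0, 2] - _center_z(f, topology)
            span = 2 * half
            z = (z + half) % span - half  # wrap into the binned range
            hist, _ = np.histogram(z, bins=edges, weights=f.masses[sel0])
            acc += hist
            area += f.box_x * f.box_y
        area /= len(in_win)
        dens = acc / len(in_win) / (bin_width * area) * _AMU_PER_NM3_TO_KG_M3
        label = selection if isinstance(selection, str) else "custom"
        out.append(DensityProfile(bin_edges=edges, density=dens, selection=label,
                                  window=(t0, t1), box_xy_area=area))
    return out[0] if single else out


def peak_separation(profile: DensityProfile) -> float:
    """Distance (nm) between the two headgroup peaks, one per half-axis.

    Each side's highest local maximum is refined by a parabolic fit
    through the three bins around it; a profile without a local
    maximum on each side of zero raises ``profile not bimodal``.
    """
    c = profile.bin_centers
    d = profile.density
    peaks = []
    for side in (c < 0, c > 0):
        idx = np.nonzero(side)[0]
        best = None
        for i in idx:
            if 0 < i < len(d) - 1 and d[i] >= d[i - 1] and d[i] >= d[i + 1] and d[i] > 0:
                if best is None or d[i] > d[best]:
                    best = i
        if best is None:
            raise ValueError("profile not bimodal")
        y0, y1, y2 = d[best - 1], d[best], d[best + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -0.5, 0.5))
        peaks.append(c[best] + shift * profile.bin_width)
    return float(peaks[1] - peaks[0])


@dataclass
class RuptureReport:
    """Outcome of water-percolation rupture detection."""

    ruptured: bool
    onset_time: float | None  # ns
    sustained_frames: int
    core_water_density_series: np.ndarray  # kg/m^3 per frame
    bulk_water_density: float  # kg/m^3
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ruptured": self.ruptured,
            "onset_time_ns": self.onset_time,
            "sustained_frames": self.sustained_frames,
            "bulk_water_density_kg_m3": self.bulk_water_density,
            "thresholds": self.thresholds,
        }


def detect_rupture(traj: Trajectory, topology: LipidTopology,
                   core_halfwidth: float = 0.5,
                   threshold_fraction: float = 0.10,
                   persistence: int = 5,
                   bin_width: float = 0.1) -> RuptureReport:
    """Detect sustained water presence in the hydrophobic core.

    Bulk water density comes from the slab ≥ 1 nm beyond the headgroup
    peaks; rupture is flagged at the first frame of the first run of at
    least ``persistence`` consecutive frames whose core water density
    exceeds ``threshold_fraction`` × bulk.
    """
    frames = list(traj)
    if len(np.asarray(topology.water_oxygens)) == 0:
        raise ValueError("no water in system")
    head = density_profile(frames, topology, selection="phosphorus",
                           bin_width=bin_width)
    sep = peak_separation(head)
    z_bulk = sep / 2 + 1.0
    half_box = head.bin_edges[-1]
    if z_bulk >= half_box - bin_width:
        raise ValueError("no bulk water region beyond the headgroup peaks")

    wsel = _selection_indices(frames[0], topology, "water")
    core = np.empty(len(frames))
    bulk = np.empty(len(frames))
    for k, f in enumerate(frames):
        z = f.positions[wsel, 2] - _center_z(f, topology)
        z = (z + half_box) % (2 * half_box) - half_box
        m = f.masses[wsel]
        area = f.box_x * f.box_y
        in_core = np.abs(z) <= core_halfwidth
        core[k] = m[in_core].sum() / (2 * core_halfwidth * area)
        in_bulk = np.abs(z) >= z_bulk
        v_bulk = 2 * (half_box - z_bulk) * area
        bulk[k] = m[in_bulk].sum() / v_bulk
    core *= _AMU_PER_NM3_TO_KG_M3
    bulk *= _AMU_PER_NM3_TO_KG_M3
    bulk_density = float(np.mean(bulk))
    if bulk_density <= 0:
        raise ValueError("no bulk water region identifiable")

    above = core > threshold_fraction * bulk_density
    onset_idx = None
    run = 0
    for k, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run == persistence:
            onset_idx = k - persistence + 1
            break
    ruptured = onset_idx is not None
    if ruptured:
        sustained = int(np.argmin(above[onset_idx:])) if not above[onset_idx:].all() \
            else int(len(above) - onset_idx)
    else:
        sustained = 0
    return RuptureReport(
        ruptured=ruptured,
        onset_time=float(frames[onset_idx].time) if ruptured else None,
        sustained_frames=sustained,
        core_water_density_series=core,
        bulk_water_density=bulk_density,
        thresholds={
            "core_halfwidth_nm": core_halfwidth,
            "threshold_fraction": threshold_fraction,
            "persistence_frames": persistence,
            "bin_width_nm": bin_width,
        },
    )
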