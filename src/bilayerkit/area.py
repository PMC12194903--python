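"""Area per lipid: projected and triangulated-3D.

The projected value A_XY_PL = L_X·L_Y/N is exact for a planar membrane
but undercounts area once the membrane undulates, because it measures
the projection rather than the surface.  The 3D value triangulates the
headgroup phosphorus positions of one leaflet in the XY plane
(Delaunay), lifts each triangle to its three-dimensional vertex
positions, and sums triangle areas, dividing by the leaflet's lipid
count.  For a flat leaflet the two coincide; an undulated surface is
always at least as large as its projection.

Periodic boundaries are handled by ghost-point tiling: phosphorus
positions are wrapped into the primary cell, copies from the eight
neighbouring images within a margin band are appended, and a triangle
is kept iff its XY centroid lies in the primary cell — so the kept
triangles tile the cell exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .frames import BoxedFrame, LipidTopology, Trajectory
from .geometry import TOP, BOTTOM, LeafletAssignment, assign_leaflets


def projected_apl(frame: BoxedFrame, n_per_leaflet: int) -> float:
    """A_XY_PL = L_X·L_Y / N (nm²)."""
    if n_per_leaflet <= 0:
        raise ValueError("n_per_leaflet must be positive")
    if frame.box_x <= 0 or frame.box_y <= 0:
        raise ValueError("zero box dimension")
    return frame.box_x * frame.box_y / n_per_leaflet


def triangulated_surface_area(points: np.ndarray, box_xy: tuple[float, float],
                              margin: float = 1.5) -> float:
    """3-D area of a periodic surface sampled at ``points`` (x, y, z).

    ``points`` need not be pre-wrapped; x and y are wrapped into
    [0, L).  ``margin`` is the ghost-band width (nm).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    lx, ly = box_xy
    pts = pts.copy()
    pts[:, 0] %= lx
    pts[:, 1] %= ly
    # break exact-lattice degeneracy: cocircular quads are tie-broken
    # inconsistently across periodic copies, which would leave gaps or
    # overlaps after clipping.  A deterministic micro-jitter (applied
    # before tiling, so the configuration stays exactly periodic) puts
    # the points in general position at ~1e-7 relative area error.
    eps = 1e-7 * min(lx, ly)
    jit = np.random.default_rng(1234567).uniform(-eps, eps, size=(len(pts), 2))
    pts[:, :2] += jit
    tiles = [pts]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            ghost = pts + np.array([dx * lx, dy * ly, 0.0])
            keep = ((ghost[:, 0] > -margin) & (ghost[:, 0] < lx + margin)
                    & (ghost[:, 1] > -margin) & (ghost[:, 1] < ly + margin))
            if np.any(keep):
                tiles.append(ghost[keep])
    tiled = np.concatenate(tiles)
    try:
        tri = Delaunay(tiled[:, :2])
    except QhullError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    simplices = tri.simplices
    cent = tiled[simplices, :2].mean(axis=1)
    keep = ((cent[:, 0] >= 0) & (cent[:, 0] < lx)
            & (cent[:, 1] >= 0) & (cent[:, 1] < ly))
    v = tiled[simplices[keep]]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def apl3d(frame: BoxedFrame, topology: LipidTopology,
          assignment: LeafletAssignment, leaflet: str,
          margin: float = 1.5) -> float:
    """Triangulated 3D area per lipid of one leaflet (nm²)."""
    idx = assignment.indices(leaflet)
    if len(idx) < 3:
        raise ValueError(f"leaflet {leaflet!r} has fewer than 3 lipids")
    p = frame.positions[topology.p_indices[idx]]
    area = triangulated_surface_area(p, (frame.box_x, frame.box_y), margin=margin)
    return area / len(idx)


@dataclass
class AplResult:
    """Per-frame area-per-lipid series with window statistics."""

    times: np.ndarray
    a_xy: np.ndarray
    apl3d_top: np.ndarray
    apl3d_bottom: np.ndarray

    @property
    def apl3d_mean_series(self) -> np.ndarray:
        return 0.5 * (self.apl3d_top + self.apl3d_bottom)

    def summary(self) -> dict:
        def ms(x):
            return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=0))}
        return {
            "a_xy": ms(self.a_xy),
            "apl3d_top": ms(self.apl3d_top),
            "apl3d_bottom": ms(self.apl3d_bottom),
            "apl3d_mean": ms(self.apl3d_mean_series),
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "time_ns": self.times,
            "a_xy_pl_nm2": self.a_xy,
            "apl3d_top_nm2": self.apl3d_top,
            "apl3d_bottom_nm2": self.apl3d_bottom,
            "apl3d_mean_nm2": self.apl3d_mean_series,
        }).to_csv(path, index=False)


def apl_series(traj: Trajectory, topology: LipidTopology,
               assignment: LeafletAssignment | None = None,
               margin: float = 1.5) -> AplResult:
    """Projected and 3D APL for every frame of a trajectory."""
    a_xy, top, bot, times = [], [], [], []
    for frame in traj:
        asg = assignment or assign_leaflets(frame, topology)
        n_ref = max(asg.n_top, asg.n_bottom)
        a_xy.append(projected_apl(frame, n_ref))
        top.append(apl3d(frame, topology, asg, TOP, margin=margin))
        bot.append(apl3d(frame, topology, asg, BOTTOM, margin=margin))
        times.append(frame.time)
    return AplResult(np.array(times), np.array(a_xy), np.array(top), np.array(bot))
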