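"""Leaflet surface reconstruction and mean-curvature maps.

The leaflet surface z(x, y) is built by binning headgroup phosphorus Z
values onto a periodic XY grid (empty cells filled by periodic
inverse-distance interpolation, optional periodic Gaussian smoothing).
The mean curvature uses the full first-fundamental-form expression

    H = [(1 + f_y²) f_xx − 2 f_x f_y f_xy + (1 + f_x²) f_yy]
        / [2 (1 + f_x² + f_y²)^{3/2}]

with periodic central finite differences — not the small-slope
Laplacian, because post-transition undulations have slopes of order 1.
With this sign, a crest (surface bulging toward +Z) has H < 0; the
three-class map therefore labels top-leaflet cells with H ≤ −h₀ convex,
H ≥ +h₀ concave and |H| < h₀ flat (the bottom leaflet is mirrored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import BoxedFrame, LipidTopology
from .geometry import TOP, LeafletAssignment

CONVEX, FLAT, CONCAVE = 1, 0, -1


def fit_leaflet_surface(frame: BoxedFrame, topology: LipidTopology,
                        assignment: LeafletAssignment, leaflet: str,
                        n_x: int = 24, n_y: int = 24,
                        smoothing_sigma: float = 0.0) -> np.ndarray:
    """Periodic height grid z(x, y) of one leaflet from its P atoms.

    ``smoothing_sigma`` is a periodic Gaussian sd in cells (0 = off).
    More than half the cells empty raises ``grid too fine``.
    """
    idx = assignment.indices(leaflet)
    if len(idx) == 0:
        raise ValueError(f"leaflet {leaflet!r} is empty")
    p = frame.positions[topology.p_indices[idx]]
    lx, ly = frame.box_x, frame.box_y
    cx = np.floor(p[:, 0] % lx / lx * n_x).astype(int) % n_x
    cy = np.floor(p[:, 1] % ly / ly * n_y).astype(int) % n_y
    zsum = np.zeros((n_x, n_y))
    cnt = np.zeros((n_x, n_y))
    np.add.at(zsum, (cx, cy), p[:, 2])
    np.add.at(cnt, (cx, cy), 1.0)
    empty = cnt == 0
    if empty.sum() > 0.5 * n_x * n_y:
        raise ValueError("grid too fine: more than half the cells are empty")
    z = np.where(empty, 0.0, zsum / np.maximum(cnt, 1.0))
    if np.any(empty):
        occ = np.array(np.nonzero(~empty)).T
        need = np.array(np.nonzero(empty)).T
        zocc = z[~empty]
        dx = (need[:, None, 0] - occ[None, :, 0]) * (lx / n_x)
        dy = (need[:, None, 1] - occ[None, :, 1]) * (ly / n_y)
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        w = 1.0 / (dx * dx + dy * dy)
        z[empty] = (w @ zocc) / w.sum(axis=1)
    if smoothing_sigma > 0:
        z = ndimage.gaussian_filter(z, smoothing_sigma, mode="wrap")
    return z


@dataclass
class CurvatureMap:
    """Gridded mean-curvature field of one leaflet."""

    heights: np.ndarray  # (n_x, n_y) nm
    mean_curvature: np.ndarray  # (n_x, n_y) nm^-1
    classes: np.ndarray  # (n_x, n_y) in {CONVEX, FLAT, CONCAVE}
    dx: float
    dy: float
    leaflet: str
    flat_band: float  # h0, nm^-1

    def class_fractions(self) -> dict[str, float]:
        n = self.classes.size
        return {
            "convex": float(np.sum(self.classes == CONVEX)) / n,
            "flat": float(np.sum(self.classes == FLAT)) / n,
            "concave": float(np.sum(self.classes == CONCAVE)) / n,
        }

    def save_text(self, path) -> None:
        np.savetxt(path, self.mean_curvature,
                   header=f"mean curvature (nm^-1), leaflet={self.leaflet}, "
                          f"dx={self.dx} dy={self.dy} flat_band={self.flat_band}")

    def render_png(self, path) -> None:
        """Three-colour contour map: blue convex, yellow flat, red concave."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        cmap = ListedColormap(["tab:blue", "gold", "tab:red"])
        norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)
        fig, ax = plt.subplots(figsize=(5, 4.4))
        nx, ny = self.classes.shape
        x = (np.arange(nx) + 0.5) * self.dx
        y = (np.arange(ny) + 0.5) * self.dy
        m = ax.pcolormesh(x, y, self.classes.T, cmap=cmap, norm=norm,
                          shading="nearest")
        cb = fig.colorbar(m, ax=ax, ticks=[-1, 0, 1])
        cb.ax.set_yticklabels(["concave", "flat", "convex"])
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("y (nm)")
        ax.set_title(f"mean curvature classes, {self.leaflet} leaflet "
                     f"(h0={self.flat_band} nm$^{{-1}}$)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def mean_curvature(heights: np.ndarray, dx: float, dy: float,
                   flat_band: float = 0.05,
                   leaflet: str = TOP) -> CurvatureMap:
    """Mean curvature of a periodic height grid by central differences."""
    f = np.asarray(heights, dtype=float)
    fx = (np.roll(f, -1, 0) - np.roll(f, 1, 0)) / (2 * dx)
    fy = (np.roll(f, -1, 1) - np.roll(f, 1, 1)) / (2 * dy)
    fxx = (np.roll(f, -1, 0) - 2 * f + np.roll(f, 1, 0)) / dx ** 2
    fyy = (np.roll(f, -1, 1) - 2 * f + np.roll(f, 1, 1)) / dy ** 2
    fxy = (np.roll(np.roll(f, -1, 0), -1, 1) - np.roll(np.roll(f, -1, 0), 1, 1)
           - np.roll(np.roll(f, 1, 0), -1, 1) + np.roll(np.roll(f, 1, 0), 1, 1)
           ) / (4 * dx * dy)
    h = ((1 + fy ** 2) * fxx - 2 * fx * fy * fxy + (1 + fx ** 2) * fyy) \
        / (2 * (1 + fx ** 2 + fy ** 2) ** 1.5)
    # bulge toward +Z has H < 0 under this sign; convex for the top leaflet
    sign = -1.0 if leaflet == TOP else 1.0
    bulge = sign * h
    classes = np.full(h.shape, FLAT, dtype=int)
    classes[bulge >= flat_band] = CONVEX
    classes[bulge <= -flat_band] = CONCAVE
    return CurvatureMap(heights=f, mean_curvature=h, classes=classes,
                        dx=dx, dy=dy, leaflet=leaflet, flat_band=flat_band)


def leaflet_curvature(frame: BoxedFrame, topology: LipidTopology,
                      assignment: LeafletAssignment, leaflet: str = TOP,
                      n_x: int = 24, n_y: int = 24,
                      smoothing_sigma: float = 0.0,
                      flat_band: float = 0.05) -> CurvatureMap:
    """Surface fit + mean curvature in one call."""
    z = fit_leaflet_surface(frame, topology, assignment, leaflet,
                            n_x=n_x, n_y=n_y, smoothing_sigma=smoothing_sigma)
    return mean_curvature(z, frame.box_x / n_x, frame.box_y / n_y,
                          flat_band=flat_band, leaflet=leaflet)
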