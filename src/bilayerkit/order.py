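"""Nematic order, leaflet directors, tilt distributions, deuterium order.

The global nematic order parameter S of a leaflet is the largest
eigenvalue of the orientational Q-tensor

    Q = (1/M) Σ (3 uᵀu − I) / 2

over the leaflet's head-to-terminal chain unit vectors, with the
director the corresponding eigenvector.  This construction needs no
reference to the bilayer normal, so it remains valid for undulated
membranes, and it is invariant under u → −u (nematic symmetry).  The
angular separation of the two leaflet directors, folded to [0°, 90°],
discriminates a tilt phase (directors parallel as lines, separation
near zero) from a cross-tilt phase (separation ≈ twice the tilt).

Tilt angles are measured from the +Z axis, arccos|v_z|, folded to
[0°, 90°].  The deuterium order parameter S_CD = ⟨(3cos²θ − 1)/2⟩ uses
C–H directions reconstructed for united-atom chains with ideal
tetrahedral geometry from the two neighbouring carbons; where the two
C–C bonds at a carbon are collinear (an idealised extended chain) the
C–H azimuth is undetermined and the average over the perpendicular
ring is taken in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import BoxedFrame, LipidTopology, Trajectory
from .geometry import (TOP, BOTTOM, ChainVectorSet, LeafletAssignment,
                       _chain_matrix, assign_leaflets, head_to_terminal_vectors,
                       minimum_image)

_HALF_HCH = np.deg2rad(109.47122 / 2)  # half the ideal tetrahedral H-C-H angle


def q_tensor(directions: np.ndarray) -> np.ndarray:
    u = np.asarray(directions, dtype=float)
    return (3.0 * (u.T @ u) / len(u) - np.eye(3)) / 2.0


def nematic_order(vectors: ChainVectorSet | np.ndarray,
                  leaflet: str | None = None) -> tuple[float, np.ndarray]:
    """Largest Q-tensor eigenvalue S and the director of one leaflet.

    The director sign is fixed so that its Z component is negative for
    the top leaflet (head→tail points inward) and positive for the
    bottom; without a leaflet label it is oriented along the mean
    vector.
    """
    if isinstance(vectors, ChainVectorSet):
        u = vectors.select(leaflet)
    else:
        u = np.asarray(vectors, dtype=float)
    if len(u) < 2:
        raise ValueError("need at least 2 vectors")
    # degenerate case: all vectors identical up to nematic sign
    dots = u @ u[0]
    if np.all(np.abs(np.abs(dots) - 1.0) < 1e-12):
        return 1.0, u[0].copy()
    w, v = np.linalg.eigh(q_tensor(u))
    s = float(w[-1])
    director = v[:, -1]
    if leaflet == TOP and director[2] > 0:
        director = -director
    elif leaflet == BOTTOM and director[2] < 0:
        director = -director
    elif leaflet is None and director @ u.mean(axis=0) < 0:
        director = -director
    return s, director


def director_separation(d_top: np.ndarray, d_bottom: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between two leaflet directors."""
    a = np.asarray(d_top, dtype=float)
    b = np.asarray(d_bottom, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length director")
    c = abs(float(a @ b) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))


@dataclass
class TiltHistogram:
    bin_edges: np.ndarray  # degrees, over [0, 90]
    frequency: np.ndarray  # sums to 1
    kind: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"bin_center_deg": self.bin_centers,
                      "frequency": self.frequency}).to_csv(path, index=False)


def tilt_angles(vectors: ChainVectorSet | np.ndarray) -> np.ndarray:
    """Per-vector tilt from the Z axis, degrees in [0, 90]."""
    u = vectors.directions if isinstance(vectors, ChainVectorSet) else np.asarray(vectors)
    return np.degrees(np.arccos(np.clip(np.abs(u[:, 2]), 0.0, 1.0)))


def tilt_distribution(vectors: ChainVectorSet | np.ndarray,
                      bins: int = 90) -> TiltHistogram:
    """Normalised tilt-angle histogram over [0°, 90°]."""
    ang = tilt_angles(vectors)
    kind = vectors.kind if isinstance(vectors, ChainVectorSet) else "custom"
    hist, edges = np.histogram(ang, bins=bins, range=(0.0, 90.0))
    total = hist.sum()
    if total == 0:
        raise ValueError("no vectors to histogram")
    return TiltHistogram(bin_edges=edges, frequency=hist / total, kind=kind)


@dataclass
class ScdProfile:
    carbon_index: np.ndarray  # interior carbon positions (2 .. L-1)
    scd: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"carbon_index": self.carbon_index,
                      "scd": self.scd}).to_csv(path, index=False)


def _scd_frame_sums(frame: BoxedFrame, topology: LipidTopology):
    """Per-interior-carbon sum of (3cos²θ−1)/2 and counts for one frame."""
    chains, _, _, _ = _chain_matrix(topology)
    cl = chains.shape[1]
    if cl < 3:
        raise ValueError("chains must have at least 3 carbons for S_CD")
    pos = frame.positions
    c_prev = pos[chains[:, :-2]]
    c_mid = pos[chains[:, 1:-1]]
    c_next = pos[chains[:, 2:]]
    b1 = minimum_image(c_prev - c_mid, frame.box)
    b2 = minimum_image(c_next - c_mid, frame.box)
    u = b2 - b1
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v = b1 + b2
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    collinear = (nv[..., 0] < 1e-9)
    cos2 = np.empty(u.shape[:2])
    # ring average where the azimuth is undetermined: <cos²θ> = (1 − u_z²)/2
    cos2[collinear] = 0.5 * (1.0 - u[collinear][:, 2] ** 2)
    if np.any(~collinear):
        uu = u[~collinear]
        vv = v[~collinear] / nv[~collinear]
        w = np.cross(uu, vv)
        w /= np.linalg.norm(w, axis=-1, keepdims=True)
        h1 = -vv * np.cos(_HALF_HCH) + w * np.sin(_HALF_HCH)
        h2 = -vv * np.cos(_HALF_HCH) - w * np.sin(_HALF_HCH)
        cos2[~collinear] = 0.5 * (h1[:, 2] ** 2 + h2[:, 2] ** 2)
    term = (3.0 * cos2 - 1.0) / 2.0  # (n_chains, cl-2)
    return term.sum(axis=0), np.full(cl - 2, term.shape[0])


def deuterium_order(traj: Trajectory | BoxedFrame, topology: LipidTopology,
                    assignment: LeafletAssignment | None = None) -> ScdProfile:
    """S_CD per interior carbon, averaged over lipids, chains and frames."""
    frames = [traj] if isinstance(traj, BoxedFrame) else list(traj)
    sums = None
    counts = None
    for f in frames:
        s, c = _scd_frame_sums(f, topology)
        sums = s if sums is None else sums + s
        counts = c if counts is None else counts + c
    scd = sums / counts
    idx = np.arange(2, topology.chain_length)
    return ScdProfile(carbon_index=idx, scd=scd)


@dataclass
class OrderResult:
    """Per-frame nematic order series with window means.

    Window values come from frame-averaged Q-tensors diagonalised once
    (ensemble-then-diagonalise), matching a *global* order parameter;
    the per-frame S series is also kept.
    """

    times: np.ndarray
    s_top: np.ndarray
    s_bottom: np.ndarray
    separation_deg: np.ndarray
    s_top_window: float
    s_bottom_window: float
    director_top: np.ndarray
    director_bottom: np.ndarray
    separation_window_deg: float

    @property
    def s_mean(self) -> np.ndarray:
        return 0.5 * (self.s_top + self.s_bottom)

    @property
    def s_window(self) -> float:
        return 0.5 * (self.s_top_window + self.s_bottom_window)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "time_ns": self.times,
            "s_top": self.s_top,
            "s_bottom": self.s_bottom,
            "s_mean": self.s_mean,
            "separation_deg": self.separation_deg,
        }).to_csv(path, index=False)


def order_series(traj: Trajectory, topology: LipidTopology,
                 assignment: LeafletAssignment | None = None) -> OrderResult:
    s_top, s_bot, sep, times = [], [], [], []
    q_top = np.zeros((3, 3))
    q_bot = np.zeros((3, 3))
    n = 0
    for frame in traj:
        asg = assignment or assign_leaflets(frame, topology)
        vecs = head_to_terminal_vectors(frame, topology, asg)
        st, dt_ = nematic_order(vecs, TOP)
        sb, db = nematic_order(vecs, BOTTOM)
        s_top.append(st)
        s_bot.append(sb)
        sep.append(director_separation(dt_, db))
        times.append(frame.time)
        q_top += q_tensor(vecs.select(TOP))
        q_bot += q_tensor(vecs.select(BOTTOM))
        n += 1
    wt, vt = np.linalg.eigh(q_top / n)
    wb, vb = np.linalg.eigh(q_bot / n)
    d_top = vt[:, -1] if vt[2, -1] < 0 else -vt[:, -1]
    d_bot = vb[:, -1] if vb[2, -1] > 0 else -vb[:, -1]
    return OrderResult(
        times=np.array(times),
        s_top=np.array(s_top), s_bottom=np.array(s_bot),
        separation_deg=np.array(sep),
        s_top_window=float(wt[-1]), s_bottom_window=float(wb[-1]),
        director_top=d_top, director_bottom=d_bot,
        separation_window_deg=director_separation(d_top, d_bot),
    )
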