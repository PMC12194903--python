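"""Orientational autocorrelation of chain-segment vectors.

The correlator is the rank-1 form f(δt) = ⟨n̂(t)·n̂(t+δt)⟩ averaged over
all segment vectors and multiple time origins; for a vector undergoing
free isotropic rotational diffusion with coefficient D_r it decays as
exp(−2·D_r·δt), and diffusion confined to a cone plateaus above zero.
The rank-2 (P₂ Legendre) variant is available behind a flag for
comparison with NMR-style observables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import LipidTopology, Trajectory
from .geometry import ChainVectorSet, alternate_carbon_vectors, assign_leaflets


@dataclass
class AcfSeries:
    lag_times: np.ndarray  # ns
    values: np.ndarray
    counts: np.ndarray  # (vector, origin) pairs per lag

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"lag_ns": self.lag_times, "acf": self.values,
                      "count": self.counts}).to_csv(path, index=False)

    def decay_rate(self, floor: float = 0.2) -> float:
        """Least-squares slope of −ln f(δt) through the origin, using
        lags with f above ``floor`` (initial exponential regime)."""
        mask = (self.lag_times > 0) & (self.values > floor)
        if not np.any(mask):
            raise ValueError("no lags in the exponential regime")
        t = self.lag_times[mask]
        y = -np.log(self.values[mask])
        return float((t @ y) / (t @ t))


def orientational_acf(vector_sets: Sequence[ChainVectorSet | np.ndarray],
                      frame_spacing: float,
                      max_lag: float | None = None,
                      origin_stride: int = 1,
                      rank: int = 1) -> AcfSeries:
    """ACF over per-frame vector sets with consistent vector ordering.

    Vectors are re-normalised per frame before correlating.  A
    ``max_lag`` at or beyond the trajectory span is truncated with a
    warning.
    """
    arrs = [vs.directions if isinstance(vs, ChainVectorSet) else np.asarray(vs)
            for vs in vector_sets]
    if len(arrs) < 2:
        raise ValueError("need at least 2 frames")
    v = np.stack(arrs)  # (T, M, 3)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    t_frames, m, _ = v.shape
    span = (t_frames - 1) * frame_spacing
    if max_lag is None:
        max_lag = span
    if max_lag > span:
        warnings.warn(f"max_lag {max_lag} ns exceeds trajectory span {span} ns; "
                      "truncating")
        max_lag = span
    n_lags = int(round(max_lag / frame_spacing)) + 1
    vals = np.empty(n_lags)
    counts = np.empty(n_lags, dtype=int)
    for l in range(n_lags):
        if origin_stride == 1:  # contiguous views, no gather copy
            d = np.einsum("omk,omk->om", v[:t_frames - l], v[l:])
        else:
            origins = np.arange(0, t_frames - l, origin_stride)
            d = np.einsum("omk,omk->om", v[origins], v[origins + l])
        if rank == 2:
            d = 1.5 * d * d - 0.5
        vals[l] = d.mean()
        counts[l] = d.size
    return AcfSeries(lag_times=np.arange(n_lags) * frame_spacing,
                     values=vals, counts=counts)


def alternate_carbon_acf(traj: Trajectory, topology: LipidTopology,
                         max_lag: float | None = None,
                         origin_stride: int = 1, step: int = 2,
                         rank: int = 1) -> AcfSeries:
    """ACF of the alternate-carbon vectors of a trajectory."""
    asg = assign_leaflets(traj[0], topology)
    sets = [alternate_carbon_vectors(f, topology, asg, step=step) for f in traj]
    return orientational_acf(sets, traj.frame_spacing, max_lag=max_lag,
                             origin_stride=origin_stride, rank=rank)
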