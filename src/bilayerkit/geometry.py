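"""Leaflet assignment and chain-vector construction.

The per-leaflet metrics (order parameters, triangulated area, σ_Z) all
start from these primitives.  The default leaflet rule is orientational
— a lipid belongs to the top leaflet if its chains point downward — and
therefore survives undulations deep enough for the leaflets' Z ranges
to overlap, where a Z-median split would misassign lipids.

All inter-atom vectors are minimum-image corrected before
normalisation, so lipids straddling a periodic boundary contribute the
same vectors as their unwrapped copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frames import BoxedFrame, LipidTopology

TOP = "top"
BOTTOM = "bottom"


class DegenerateLeafletError(ValueError):
    pass


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary periodic image."""
    return disp - box * np.round(disp / box)


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels (aligned with ``topology.lipids``)."""

    labels: np.ndarray  # (n_lipids,) of {"top", "bottom"}

    @property
    def n_top(self) -> int:
        return int(np.sum(self.labels == TOP))

    @property
    def n_bottom(self) -> int:
        return int(np.sum(self.labels == BOTTOM))

    def indices(self, leaflet: str) -> np.ndarray:
        return np.nonzero(self.labels == leaflet)[0]


@dataclass
class ChainVectorSet:
    """Unit chain-segment directions with their provenance labels.

    ``kind`` is ``"head-to-terminal"`` (two vectors per lipid, P atom to
    each chain's terminal carbon) or ``"alternate-carbon"`` (C_i to
    C_{i+step} along each chain).
    """

    kind: str
    directions: np.ndarray  # (m, 3) unit vectors
    lipid_ids: np.ndarray  # (m,) index into topology.lipids
    chain_ids: np.ndarray  # (m,)
    segment_ids: np.ndarray  # (m,)
    leaflets: np.ndarray  # (m,) labels

    def __len__(self) -> int:
        return len(self.directions)

    def select(self, leaflet: str | None) -> np.ndarray:
        if leaflet is None:
            return self.directions
        return self.directions[self.leaflets == leaflet]


def _chain_matrix(topology: LipidTopology):
    """(n_chains, L) carbon-index matrix plus per-chain lipid/chain ids."""
    rows, lids, cids, anchors = [], [], [], []
    for li, l in enumerate(topology.lipids):
        for ci, ch in enumerate(l.chains):
            rows.append(ch)
            lids.append(li)
            cids.append(ci)
            anchors.append(l.phosphorus)
    return (np.array(rows, dtype=int), np.array(lids, dtype=int),
            np.array(cids, dtype=int), np.array(anchors, dtype=int))


def assign_leaflets(frame: BoxedFrame, topology: LipidTopology,
                    method: str = "orientation") -> LeafletAssignment:
    """Assign each lipid to the top or bottom leaflet.

    ``orientation`` (default): top if the mean of the lipid's
    head-to-terminal chain vectors has negative Z (chains point down
    toward the midplane).  ``zmedian``: split P-atom Z on the median.
    """
    if topology.n_lipids == 0:
        raise DegenerateLeafletError("no lipids to assign")
    if method == "orientation":
        chains, lids, _, anchors = _chain_matrix(topology)
        tail = frame.positions[chains[:, -1]]
        head = frame.positions[anchors]
        v = minimum_image(tail - head, frame.box)
        mean_z = np.zeros(topology.n_lipids)
        np.add.at(mean_z, lids, v[:, 2])
        labels = np.where(mean_z < 0, TOP, BOTTOM)
    elif method == "zmedian":
        z = frame.positions[topology.p_indices, 2]
        labels = np.where(z > np.median(z), TOP, BOTTOM)
    else:
        raise ValueError(f"unknown leaflet method {method!r}")
    labels = labels.astype(object)
    asg = LeafletAssignment(labels=np.array(labels, dtype=object))
    if asg.n_top == 0 or asg.n_bottom == 0:
        raise DegenerateLeafletError(
            f"degenerate leaflet split: {asg.n_top} top / {asg.n_bottom} bottom")
    return asg


def head_to_terminal_vectors(frame: BoxedFrame, topology: LipidTopology,
                             assignment: LeafletAssignment) -> ChainVectorSet:
    """Unit vectors from each lipid's P atom to each chain's terminal carbon."""
    chains, lids, cids, anchors = _chain_matrix(topology)
    v = minimum_image(frame.positions[chains[:, -1]] - frame.positions[anchors],
                      frame.box)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-9):
        bad = topology.lipids[int(lids[np.argmin(norms)])].resid
        raise ValueError(f"zero-length head-to-terminal vector in lipid {bad}")
    return ChainVectorSet(
        kind="head-to-terminal",
        directions=v / norms[:, None],
        lipid_ids=lids,
        chain_ids=cids,
        segment_ids=np.zeros(len(v), dtype=int),
        leaflets=assignment.labels[lids],
    )


def alternate_carbon_vectors(frame: BoxedFrame, topology: LipidTopology,
                             assignment: LeafletAssignment,
                             step: int = 2) -> ChainVectorSet:
    """Unit vectors C_i → C_{i+step} along each acyl chain (step 2 default)."""
    cl = topology.chain_length
    if cl <= step:
        warnings.warn(f"chain length {cl} too short for step-{step} segment vectors")
        empty = np.empty((0, 3))
        zi = np.empty(0, dtype=int)
        return ChainVectorSet("alternate-carbon", empty, zi, zi, zi,
                              np.empty(0, dtype=object))
    chains, lids, cids, _ = _chain_matrix(topology)
    a = frame.positions[chains[:, :-step]]  # (n_chains, cl-step, 3)
    b = frame.positions[chains[:, step:]]
    v = minimum_image(b - a, frame.box).reshape(-1, 3)
    nseg = cl - step
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-9):
        bad = topology.lipids[int(np.repeat(lids, nseg)[np.argmin(norms)])].resid
        raise ValueError(f"coincident chain carbons in lipid {bad}")
    lip = np.repeat(lids, nseg)
    return ChainVectorSet(
        kind="alternate-carbon",
        directions=v / norms[:, None],
        lipid_ids=lip,
        chain_ids=np.repeat(cids, nseg),
        segment_ids=np.tile(np.arange(nseg), len(chains)),
        leaflets=assignment.labels[lip],
    )
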