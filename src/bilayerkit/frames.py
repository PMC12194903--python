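"""Trajectory/topology data model and coordinate-format I/O.

All lengths are nanometres and all times nanoseconds internally; PDB
Ångström values are converted on read.  Only orthorhombic boxes are
supported — the systems under study are rectangular slabs, and silently
projecting a sheared (triclinic) cell would corrupt every area metric.

Reading of GRO/PDB single frames and XTC/TRR/multi-GRO trajectories is
delegated to MDAnalysis; this module owns only the conversion into the
package's plain containers and the validation of their invariants.
Coordinates are never wrapped on read: periodic wrapping is an explicit
choice of each downstream metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .conventions import DEFAULT_CONVENTION, NamingConvention

_A_TO_NM = 0.1
_PS_TO_NS = 1e-3


class FormatError(ValueError):
    """Raised for malformed or unsupported coordinate input."""


@dataclass
class BoxedFrame:
    """One configuration: orthorhombic box, positions, names, masses."""

    box: np.ndarray  # (3,) nm
    positions: np.ndarray  # (n, 3) nm
    names: np.ndarray  # (n,) str
    resnames: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int
    masses: np.ndarray  # (n,) amu
    time: float = 0.0  # ns
    pressure_label: float | None = None  # bar

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,):
            raise FormatError("box must be three orthorhombic lengths")
        if not np.all(self.box > 0):
            raise FormatError(f"box lengths must be positive, got {self.box}")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("non-finite coordinates")
        n = len(self.positions)
        for arr in (self.names, self.resnames, self.resids, self.masses):
            if len(arr) != n:
                raise FormatError("per-atom arrays must share one length")

    @property
    def box_x(self) -> float:
        return float(self.box[0])

    @property
    def box_y(self) -> float:
        return float(self.box[1])

    @property
    def box_z(self) -> float:
        return float(self.box[2])

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclass
class Trajectory:
    """Ordered frame sequence with uniform atom count and increasing times."""

    frames: list[BoxedFrame]

    def __post_init__(self) -> None:
        if self.frames:
            n = self.frames[0].n_atoms
            if any(f.n_atoms != n for f in self.frames):
                raise FormatError("atom count varies across frames")
            times = self.times
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise FormatError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BoxedFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def frame_spacing(self) -> float:
        """Time between saved frames (ns); 0.1 ns for a single frame,
        matching the common 100 ps save interval."""
        if len(self.frames) < 2:
            return 0.1
        return float(np.mean(np.diff(self.times)))


@dataclass
class Lipid:
    resid: int
    phosphorus: int
    nitrogen: int
    chains: tuple[np.ndarray, ...]  # ordered carbon indices, head-proximal first


@dataclass
class LipidTopology:
    """Per-lipid atom-index map enabling all vector constructions."""

    lipids: list[Lipid]
    water_oxygens: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    @property
    def chain_length(self) -> int:
        if not self.lipids:
            return 0
        return len(self.lipids[0].chains[0])

    @property
    def p_indices(self) -> np.ndarray:
        return np.array([l.phosphorus for l in self.lipids], dtype=int)

    def lipid_atom_indices(self) -> np.ndarray:
        """All atom indices belonging to lipids."""
        out: list[int] = []
        for l in self.lipids:
            out.append(l.phosphorus)
            out.append(l.nitrogen)
            for ch in l.chains:
                out.extend(int(i) for i in ch)
        return np.array(sorted(set(out)), dtype=int)


# ---------------------------------------------------------------------------
# readers / writers


def _check_orthorhombic(dimensions: np.ndarray, path) -> np.ndarray:
    if dimensions is None or not np.all(dimensions[:3] > 0):
        raise FormatError(f"{path}: missing box record")
    if not np.allclose(dimensions[3:6], 90.0, atol=1e-3):
        raise FormatError(f"{path}: triclinic box unsupported (angles {dimensions[3:6]})")
    return dimensions[:3] * _A_TO_NM


def _frame_from_universe(u, conv: NamingConvention, time_ns: float | None = None) -> BoxedFrame:
    ag = u.atoms
    box = _check_orthorhombic(u.dimensions, getattr(u, "filename", "<universe>"))
    names = np.array(ag.names, dtype=object)
    terminal = _terminal_mask(names, np.asarray(ag.resids), conv)
    masses = np.array(
        [conv.mass_of(nm, terminal=t) for nm, t in zip(names, terminal)], dtype=float
    )
    t = time_ns
    if t is None:
        t = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0) * _PS_TO_NS
    return BoxedFrame(
        box=box,
        positions=ag.positions * _A_TO_NM,
        names=names,
        resnames=np.array(ag.resnames, dtype=object),
        resids=np.array(ag.resids, dtype=int),
        masses=masses,
        time=t,
    )


def _terminal_mask(names: np.ndarray, resids: np.ndarray,
                   conv: NamingConvention) -> np.ndarray:
    """True for the last carbon of each chain (gets the CH3 mass)."""
    terminal = np.zeros(len(names), dtype=bool)
    pos_info = [conv.chain_position(str(nm)) for nm in names]
    chain_max: dict[tuple[int, int], int] = {}
    for i, info in enumerate(pos_info):
        if info is not None:
            key = (int(resids[i]), info[0])
            chain_max[key] = max(chain_max.get(key, 0), info[1])
    for i, info in enumerate(pos_info):
        if info is not None and info[1] == chain_max[(int(resids[i]), info[0])]:
            terminal[i] = True
    return terminal


def _parse_gro_blocks(path, conv: NamingConvention) -> Iterator[BoxedFrame]:
    """Parse a (possibly multi-frame) fixed-column GRO file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{i + 2}: bad atom count line") from exc
        if i + 2 + natoms >= len(lines):
            warnings.warn(f"{path}: truncated trailing frame dropped")
            break
        names, resnames, resids, pos = [], [], [], []
        for k in range(natoms):
            ln = lines[i + 2 + k]
            try:
                resids.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                pos.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}:{i + 3 + k}: malformed fixed-column GRO line") from exc
        box_tokens = lines[i + 2 + natoms].split()
        if len(box_tokens) not in (3, 9):
            raise FormatError(f"{path}:{i + 3 + natoms}: missing box line")
        vals = [float(t) for t in box_tokens]
        if len(vals) == 9 and any(abs(v) > 1e-9 for v in vals[3:]):
            raise FormatError(f"{path}:{i + 3 + natoms}: triclinic box unsupported")
        time_ns = frame_no * 0.1
        if "t=" in title:
            try:
                time_ns = float(title.split("t=")[1].split()[0]) * _PS_TO_NS
            except (ValueError, IndexError):
                pass
        names_a = np.array(names, dtype=object)
        resids_a = np.array(resids, dtype=int)
        term = _terminal_mask(names_a, resids_a, conv)
        masses = np.array([conv.mass_of(str(nm), terminal=t)
                           for nm, t in zip(names_a, term)], dtype=float)
        yield BoxedFrame(
            box=np.array(vals[:3]), positions=np.array(pos),
            names=names_a, resnames=np.array(resnames, dtype=object),
            resids=resids_a, masses=masses, time=time_ns)
        i += natoms + 3
        frame_no += 1


def read_frame(path, fmt: str | None = None,
               convention: NamingConvention = DEFAULT_CONVENTION) -> BoxedFrame:
    """Read a single GRO or PDB configuration.

    Positions are returned in nm (PDB Å converted); the box comes from
    the GRO box line or the PDB CRYST1 record.  Malformed fixed-column
    GRO lines raise a :class:`FormatError` naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "gro":
        frame = next(_parse_gro_blocks(path, convention), None)
        if frame is None:
            raise FormatError(f"{path}: no frame found")
        return frame
    if fmt != "pdb":
        raise FormatError(f"unsupported single-frame format {fmt!r}")
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except FormatError:
            raise
        except Exception as exc:  # surface the parser's line diagnostics
            raise FormatError(f"{path}: {exc}") from exc
    return _frame_from_universe(u, convention, time_ns=0.0)


def read_trajectory(topology_path, trajectory_path=None, fmt: str | None = None,
                    convention: NamingConvention = DEFAULT_CONVENTION) -> Trajectory:
    """Read a trajectory (XTC/TRR against a topology, or multi-frame GRO).

    Times are converted to ns.  An atom-count mismatch between topology
    and trajectory raises; a truncated trailing frame is dropped with a
    warning (MDAnalysis already stops at the last intact frame).
    """
    if trajectory_path is None and (
            fmt in ("gro", "multi-gro")
            or (fmt is None and str(topology_path).lower().endswith(".gro"))):
        frames = list(_parse_gro_blocks(topology_path, convention))
        if not frames:
            raise FormatError(f"{topology_path}: no frames found")
        times = np.array([f.time for f in frames])
        if len(frames) > 1 and not np.all(np.diff(times) > 0):
            for i, f in enumerate(frames):
                f.time = i * 0.1
        return Trajectory(frames)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(trajectory_path), format=fmt)
        except FormatError:
            raise
        except Exception as exc:
            msg = str(exc)
            if "number of atoms" in msg.lower() or "mismatch" in msg.lower():
                raise FormatError(f"atom-count mismatch: {msg}") from exc
            raise FormatError(msg) from exc
        frames = []
        for ts in u.trajectory:
            frames.append(_frame_from_universe(u, convention))
    # normalize times: some writers leave all-zero times
    times = np.array([f.time for f in frames])
    if len(frames) > 1 and not np.all(np.diff(times) > 0):
        for i, f in enumerate(frames):
            f.time = i * 0.1
    return Trajectory(frames)


def write_frame(frame: BoxedFrame, path) -> None:
    """Write one frame as fixed-column GRO (nm, 3 decimals)."""
    with open(path, "w") as fh:
        _write_gro_frame(fh, frame)


def write_trajectory(traj: Trajectory | Iterable[BoxedFrame], path) -> None:
    """Write a multi-frame GRO file (concatenated GRO records)."""
    with open(path, "w") as fh:
        for frame in traj:
            _write_gro_frame(fh, frame)


def _write_gro_frame(fh, frame: BoxedFrame) -> None:
    fh.write(f"bilayerkit frame t= {frame.time * 1e3:.3f} ps\n")
    fh.write(f"{frame.n_atoms:5d}\n")
    for i in range(frame.n_atoms):
        resid = int(frame.resids[i]) % 100000
        atomid = (i + 1) % 100000
        x, y, z = frame.positions[i]
        fh.write(
            f"{resid:5d}{str(frame.resnames[i])[:5]:<5s}"
            f"{str(frame.names[i])[:5]:>5s}{atomid:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# topology extraction


def extract_lipid_topology(frame: BoxedFrame,
                           convention: NamingConvention = DEFAULT_CONVENTION,
                           ) -> LipidTopology:
    """Build the per-lipid atom-index map from atom names.

    A residue is a lipid if it contains a phosphorus-named atom (or if
    its residue name is in the convention's ``lipid_resnames``).  Each
    lipid must expose a nitrogen and two non-empty carbon chains; a
    missing phosphorus in a declared lipid residue or ragged chain
    lengths are reported.
    """
    by_res: dict[int, list[int]] = {}
    for i, rid in enumerate(frame.resids):
        by_res.setdefault(int(rid), []).append(i)

    lipids: list[Lipid] = []
    waters: list[int] = []
    chain_lengths: set[int] = set()
    for rid, idxs in sorted(by_res.items()):
        names = [str(frame.names[i]) for i in idxs]
        w = [i for i, nm in zip(idxs, names) if nm in convention.water_oxygen_names]
        if w and len(w) == len(idxs):
            waters.extend(w)
            continue
        declared = (convention.lipid_resnames is not None
                    and str(frame.resnames[idxs[0]]) in convention.lipid_resnames)
        p = [i for i, nm in zip(idxs, names) if nm in convention.phosphorus_names]
        has_chain = any(convention.chain_position(nm) for nm in names)
        if not p:
            if declared or has_chain:
                raise FormatError(f"lipid residue {rid} lacks a phosphorus atom")
            waters.extend(w)
            continue
        n = [i for i, nm in zip(idxs, names) if nm in convention.nitrogen_names]
        if not n:
            raise FormatError(f"lipid residue {rid} lacks a nitrogen atom")
        chains: dict[int, dict[int, int]] = {}
        for i, nm in zip(idxs, names):
            info = convention.chain_position(nm)
            if info is not None:
                ci, pos = info
                if pos in chains.setdefault(ci, {}):
                    raise FormatError(f"residue {rid}: duplicate chain carbon {nm}")
                chains[ci][pos] = i
        if len(chains) < 2 or any(not c for c in chains.values()):
            raise FormatError(f"lipid residue {rid}: fewer than two acyl chains found")
        ordered = []
        for ci in sorted(chains):
            pos_sorted = sorted(chains[ci])
            if pos_sorted != list(range(pos_sorted[0], pos_sorted[-1] + 1)):
                raise FormatError(f"lipid residue {rid}: chain {ci} has a gap "
                                  f"(missing carbon)")
            ordered.append(np.array([chains[ci][p_] for p_ in pos_sorted], dtype=int))
            chain_lengths.add(len(pos_sorted))
        lipids.append(Lipid(resid=rid, phosphorus=p[0], nitrogen=n[0],
                            chains=tuple(ordered)))
        waters.extend(w)

    if len(chain_lengths) > 1:
        warnings.warn(f"ragged acyl-chain lengths across lipids: {sorted(chain_lengths)}")
    topo = LipidTopology(lipids=lipids, water_oxygens=np.array(sorted(waters), dtype=int))
    # index sanity
    seen: set[int] = set()
    for l in topo.lipids:
        for ch in l.chains:
            for i in ch:
                if int(i) in seen:
                    raise FormatError(f"atom index {i} appears in two chains")
                seen.add(int(i))
    return topo
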