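"""Core data model: particle topology, frames, trajectories, and file I/O.

All internal lengths are nanometres and times picoseconds; PDB input
(Ångström) is converted on read.  Coordinates are stored exactly as read —
analyses apply the minimum-image convention where distances are computed,
never by rewrapping stored positions.  Boxes are orthorhombic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .roles import Role, RoleAssignment, RoleDialect

__all__ = [
    "ParticleTopology",
    "Frame",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "select",
    "analysis_window",
]

_ANGSTROM_TO_NM = 0.1


@dataclass
class ParticleTopology:
    """Array-backed per-particle metadata.

    ``helix_id``, ``strand_id`` and ``tail_position`` use ``-1`` as the
    "unset" sentinel.  ``names``/``resnames`` keep the source naming so that
    structures round-trip through the writers.
    """

    roles: np.ndarray          # object array of Role
    molecule_id: np.ndarray    # int
    helix_id: np.ndarray       # int, -1 = unset; set iff role is a DNT role
    strand_id: np.ndarray      # int, -1 = unset
    residue_index: np.ndarray  # int
    bead_radius: np.ndarray    # float, nm
    tail_position: np.ndarray  # int, -1 = unset
    names: np.ndarray          # str
    resnames: np.ndarray       # str

    def __post_init__(self):
        n = len(self.roles)
        for f in ("molecule_id", "helix_id", "strand_id", "residue_index",
                  "bead_radius", "tail_position", "names", "resnames"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"topology field {f} has wrong length")

    def __len__(self) -> int:
        return len(self.roles)

    @property
    def n_particles(self) -> int:
        return len(self.roles)

    def role_mask(self, roles: Role | Iterable[Role]) -> np.ndarray:
        if isinstance(roles, Role):
            roles = {roles}
        roles = set(roles)
        return np.fromiter((r in roles for r in self.roles), bool, len(self))

    @classmethod
    def from_assignments(
        cls,
        assignments: Sequence[RoleAssignment],
        molecule_id,
        residue_index,
        names,
        resnames,
        helix_id=None,
        strand_id=None,
    ) -> "ParticleTopology":
        n = len(assignments)
        return cls(
            roles=np.array([a.role for a in assignments], dtype=object),
            molecule_id=np.asarray(molecule_id, dtype=int),
            helix_id=np.full(n, -1, int) if helix_id is None else np.asarray(helix_id, int),
            strand_id=np.full(n, -1, int) if strand_id is None else np.asarray(strand_id, int),
            residue_index=np.asarray(residue_index, dtype=int),
            bead_radius=np.array(
                [a.bead_radius if a.bead_radius is not None else np.nan for a in assignments]
            ),
            tail_position=np.array(
                [a.tail_position if a.tail_position is not None else -1 for a in assignments],
                dtype=int,
            ),
            names=np.asarray(names, dtype=object),
            resnames=np.asarray(resnames, dtype=object),
        )


@dataclass
class Frame:
    """One configuration: time (ps), box lengths (nm, orthorhombic), positions (nm)."""

    time: float
    box: np.ndarray        # (3,)
    positions: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.box = np.asarray(self.box, float)
        self.positions = np.asarray(self.positions, float)
        if self.box.shape != (3,):
            raise ValueError("box must hold three orthorhombic lengths")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")


@dataclass
class Trajectory:
    """Ordered frames over one topology; times strictly increasing."""

    topology: ParticleTopology
    frames: list[Frame]

    def __post_init__(self):
        n = self.topology.n_particles
        for i, fr in enumerate(self.frames):
            if fr.positions.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.positions.shape[0]} particles, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def frame_interval(self) -> Optional[float]:
        """Constant frame spacing in ps, or None for a single frame.

        Raises if the spacing varies by more than 1 % of the mean interval.
        """
        if len(self.frames) < 2:
            return None
        dt = np.diff(self.times)
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            raise ValueError("frame interval is not constant")
        return float(dt.mean())

    def subset(self, indices) -> "Trajectory":
        return Trajectory(self.topology, [self.frames[i] for i in indices])


# ---------------------------------------------------------------------------
# readers / writers

def _tail_position_heuristic(names, assignments):
    """Fill atomistic tail positions from trailing digits of Cxy tail names."""
    for name, a in zip(names, assignments):
        if a.role in (Role.LIPID_TAIL_SN1, Role.LIPID_TAIL_SN2) and a.tail_position is None:
            m = re.match(r"^C[23](\d+)$", name)
            if m:
                a.tail_position = int(m.group(1)) - 1


def _universe(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def read_structure(path, dialect: RoleDialect, on_unknown: str = "error"):
    """Read a PDB or GRO structure into ``(ParticleTopology, Frame)``.

    Every record is mapped to a role through ``dialect``; unmapped names raise
    :class:`~dntpore.roles.UnknownNamesError` unless ``on_unknown='other'``.
    Coordinates are converted to nm regardless of the source unit convention.
    """
    u = _universe(path)
    names = [str(n) for n in u.atoms.names]
    resnames = [str(r) for r in u.atoms.resnames]
    assignments = dialect.assign(resnames, names, on_unknown=on_unknown)
    _tail_position_heuristic(names, assignments)
    resindices = np.asarray(u.atoms.resindices, int)
    top = ParticleTopology.from_assignments(
        assignments,
        molecule_id=resindices,
        residue_index=resindices,
        names=names,
        resnames=resnames,
    )
    if u.dimensions is None or np.any(u.dimensions[:3] <= 0):
        raise ValueError(f"{path}: structure has no box definition")
    frame = Frame(
        time=0.0,
        box=u.dimensions[:3] * _ANGSTROM_TO_NM,
        positions=u.atoms.positions * _ANGSTROM_TO_NM,
    )
    return top, frame


def write_structure(path, topology: ParticleTopology, frame: Frame) -> None:
    """Write a structure back to GRO (nm) via MDAnalysis."""
    import MDAnalysis as mda

    n = topology.n_particles
    uniq, inverse = np.unique(topology.residue_index, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=inverse, trajectory=True
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.names])
    res_names = [""] * len(uniq)
    for i, ridx in enumerate(inverse):
        res_names[ridx] = str(topology.resnames[i])
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", (np.arange(len(uniq)) % 99999) + 1)
    u.atoms.positions = frame.positions / _ANGSTROM_TO_NM
    u.dimensions = np.array(
        [*(frame.box / _ANGSTROM_TO_NM), 90.0, 90.0, 90.0], dtype=np.float32
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(
    path,
    topology: ParticleTopology,
    frame_interval: Optional[float] = None,
    start: int = 0,
    stop: Optional[int] = None,
    stride: int = 1,
) -> Trajectory:
    """Read a multi-frame PDB/GRO or XTC trajectory.

    ``frame_interval`` (ps) supplies times for formats that do not store them;
    stored times win when present and nonzero.  ``start``/``stop``/``stride``
    select a frame range before times are assigned.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    n = topology.n_particles
    raw: list[tuple[Optional[float], np.ndarray, np.ndarray]] = []

    if suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader

        reader = XTCReader(str(path))
        for ts in reader:
            raw.append((float(ts.time), ts.dimensions[:3] * _ANGSTROM_TO_NM,
                        ts.positions * _ANGSTROM_TO_NM))
        reader.close()
    elif suffix == ".gro":
        import mdtraj.formats

        with mdtraj.formats.GroTrajectoryFile(str(path)) as fh:
            coords, times, cells = fh.read()
        for i in range(coords.shape[0]):
            t = float(times[i]) if times is not None else None
            raw.append((t, np.diag(cells[i]).astype(float), coords[i].astype(float)))
    elif suffix == ".pdb":
        u = _universe(path)
        # MDAnalysis only applies CRYST1 records found inside MODEL blocks;
        # fall back to a header CRYST1 (as written by its own multiframe writer)
        last_box = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    last_box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    ) * _ANGSTROM_TO_NM
                    break
                if line.startswith("MODEL"):
                    break
        for ts in u.trajectory:
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                last_box = ts.dimensions[:3] * _ANGSTROM_TO_NM
            if last_box is None:
                raise ValueError(f"{path}: no box record before frame {len(raw)}")
            raw.append((None, last_box.copy(), ts.positions * _ANGSTROM_TO_NM))
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")

    for i, (_, _, pos) in enumerate(raw):
        if pos.shape[0] != n:
            raise ValueError(
                f"frame {i}: particle count {pos.shape[0]} does not match "
                f"topology ({n})"
            )

    raw = raw[start:stop:stride]
    stored_times = [t for t, _, _ in raw]
    have_times = all(t is not None for t in stored_times) and (
        len(raw) < 2 or stored_times[-1] > stored_times[0]
    )
    frames = []
    for i, (t, box, pos) in enumerate(raw):
        if have_times:
            time = t
        elif frame_interval is not None:
            time = (start + i * stride) * frame_interval
        else:
            time = float(start + i * stride)
        frames.append(Frame(time=time, box=box, positions=pos))
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# selection and windows

def select(
    topology: ParticleTopology,
    roles: Role | Iterable[Role] | None = None,
    helix_id: Optional[int] = None,
    strand_id: Optional[int] = None,
    molecule_id: Optional[int] = None,
    residue_index: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Deterministic, order-preserving particle selection (predicate conjunction)."""
    keep = np.ones(topology.n_particles, bool)
    if roles is not None:
        keep &= topology.role_mask(roles)
    if helix_id is not None:
        keep &= topology.helix_id == helix_id
    if strand_id is not None:
        keep &= topology.strand_id == strand_id
    if molecule_id is not None:
        keep &= topology.molecule_id == molecule_id
    if residue_index is not None:
        keep &= topology.residue_index == residue_index
    if mask is not None:
        keep &= np.asarray(mask, bool)
    return np.nonzero(keep)[0]


def analysis_window(traj: Trajectory, last_t_ns: float) -> Trajectory:
    """Trailing sub-trajectory spanning the last ``last_t_ns`` nanoseconds.

    The window is ``[t_end - last_t, t_end]`` with both endpoint frames
    included, so a span sampled every ``dt`` yields ``last_t/dt + 1`` frames.
    """
    times = traj.times
    span_ns = (times[-1] - times[0]) / 1000.0
    if last_t_ns > span_ns + 1e-9:
        raise ValueError(
            f"requested window of {last_t_ns} ns exceeds trajectory span of "
            f"{span_ns:g} ns"
        )
    t0 = times[-1] - last_t_ns * 1000.0
    idx = np.nonzero(times >= t0 - 1e-9)[0]
    return traj.subset(idx)
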