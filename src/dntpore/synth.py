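"""Synthetic membrane/DNT systems with known ground truth.

These generators emulate the statistical structure of coarse-grained
simulations of a six-duplex DNA nanotube spanning a PC bilayer — bilayer
thinning near the tube wall, acyl-tail orientational order, lumen cation
selectivity, tube tilt, COM-displacement relaxation and SMD force traces —
without running any dynamics.  Lipids are rigid templated bead chains
jittered per frame; every generated parameter is recorded in a GroundTruth
mapping so the analysis modules can be validated by parameter recovery.

All generators are deterministic: the same parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .builder import DNTModel, build_hexagonal_scaffold, model_to_topology
from .model import Frame, ParticleTopology, Trajectory
from .roles import Role, RoleAssignment

__all__ = [
    "MembraneSystemParams",
    "SMDTraceParams",
    "ForceTrace",
    "generate_membrane_system",
    "generate_smd_trace",
    "generate_displacement_trace",
    "generate_residence_trajectory",
]

_TAIL_BOND = 0.47   # nm, CG bond length between consecutive tail beads
_HEAD_BOND = 0.35   # nm, headgroup stacking distance


@dataclass
class MembraneSystemParams:
    """Study conditions for the synthetic membrane system.

    Defaults mirror the simulated system: an ~18 × 18 × 25 nm box with the
    bilayer normal along z, a PC bilayer of unperturbed phosphate–phosphate
    thickness ``bilayer_thickness_h0``, thinning next to the tube wall
    following h(r) = h0 − A·exp(−(r − r_wall)/λ), and a NaCl electrolyte
    whose lumen composition is cation-enriched.
    """

    box: tuple[float, float, float] = (18.0, 18.0, 25.0)
    bilayer_thickness_h0: float = 4.0     # nm
    thinning_amplitude: float = 0.8       # nm (A)
    thinning_decay: float = 1.0           # nm (lambda)
    lipid_count: int = 400                # per leaflet
    tube: Optional[DNTModel] = None       # default: 6-helix, d = 2.0 nm
    tilt_angle: float = 0.0               # degrees, about x
    tilt_jitter_sd: float = 0.0           # degrees, per-frame
    lumen_cation_anion_ratio: float = 14.0
    lumen_ion_count: int = 150
    bulk_ion_pairs: int = 200
    water_count: int = 2000
    order_param_target: float | Sequence[float] = 0.5  # S, scalar or per zone
    order_zone_edges: Optional[Sequence[float]] = None  # nm radii for zones
    jitter_sd: float = 0.05               # nm thermal jitter per frame
    seed: int = 0

    def __post_init__(self):
        if self.bilayer_thickness_h0 <= 0:
            raise ValueError("bilayer thickness must be positive")
        if self.lumen_cation_anion_ratio < 0:
            raise ValueError("lumen cation:anion ratio must be >= 0")
        for name in ("lipid_count", "lumen_ion_count", "bulk_ion_pairs",
                     "water_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SMDTraceParams:
    """Constant-velocity pulling trace parameters (forces in kJ mol⁻¹ nm⁻¹)."""

    pull_velocity: float = 10.0     # nm per microsecond
    entry_peak: float = 1000.0
    exit_peak: float = 400.0
    plateau_force: float = 0.0
    noise_sd: float = 0.0
    peak_width: float = 1.0         # nm, Gaussian width in COM-z
    bilayer_half_thickness: float = 2.0  # nm; bumps centred at -/+ this z
    start_z: float = -10.0          # nm, initial band COM relative to bilayer
    seed: int = 0

    def __post_init__(self):
        if self.pull_velocity <= 0:
            raise ValueError("pull velocity must be positive")
        if self.entry_peak < 0 or self.exit_peak < 0:
            raise ValueError("peak heights must be >= 0")


@dataclass
class ForceTrace:
    """SMD pulling record: applied force and pulled-group COM versus time."""

    time: np.ndarray      # ps
    force: np.ndarray     # kJ mol^-1 nm^-1
    com_z: np.ndarray     # nm
    pull_velocity: float  # nm per microsecond


def _lipid_template(rng, r, h_r, sign, order_target):
    """Bead stack for one lipid: NC3, PO4, GL1, GL2, 4 sn1 + 4 sn2 tail beads.

    Tail bonds all make the polar angle whose order parameter equals
    ``order_target`` (cos²θ = (2S+1)/3), with a random azimuth per chain, so
    the generated S is exact up to jitter.
    """
    z_po4 = sign * h_r / 2.0
    cos_t = np.sqrt((2.0 * order_target + 1.0) / 3.0)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
    beads = [
        ("NC3", [0.0, 0.0, z_po4 + sign * _HEAD_BOND]),
        ("PO4", [0.0, 0.0, z_po4]),
        ("GL1", [0.0, 0.0, z_po4 - sign * _HEAD_BOND]),
        ("GL2", [0.12, 0.0, z_po4 - sign * _HEAD_BOND]),
    ]
    for chain, x0 in (("A", 0.0), ("B", 0.12)):
        az = rng.uniform(0, 2 * np.pi)
        step = _TAIL_BOND * np.array(
            [sin_t * np.cos(az), sin_t * np.sin(az), -sign * cos_t]
        )
        start = np.array([x0, 0.0, z_po4 - sign * (_HEAD_BOND + 0.1)])
        for k in range(1, 5):
            name = ("D2A" if (chain == "A" and k == 2) else f"C{k}{chain}")
            beads.append((name, start + (k - 1) * step))
    return beads


_LIPID_ROLE = {
    "NC3": (Role.LIPID_NC3, None),
    "PO4": (Role.LIPID_PO4, None),
    "GL1": (Role.LIPID_GLY, None),
    "GL2": (Role.LIPID_GLY, None),
    "C1A": (Role.LIPID_TAIL_SN2, 1), "D2A": (Role.LIPID_TAIL_SN2, 2),
    "C3A": (Role.LIPID_TAIL_SN2, 3), "C4A": (Role.LIPID_TAIL_SN2, 4),
    "C1B": (Role.LIPID_TAIL_SN1, 1), "C2B": (Role.LIPID_TAIL_SN1, 2),
    "C3B": (Role.LIPID_TAIL_SN1, 3), "C4B": (Role.LIPID_TAIL_SN1, 4),
}


def _order_target_at(params: MembraneSystemParams, r: float) -> float:
    tgt = params.order_param_target
    if np.isscalar(tgt):
        return float(tgt)
    edges = params.order_zone_edges
    if edges is None:
        raise ValueError("per-zone order targets require order_zone_edges")
    zone = int(np.searchsorted(np.asarray(edges), r))
    return float(np.asarray(tgt)[min(zone, len(tgt) - 1)])


def generate_membrane_system(
    params: MembraneSystemParams,
    n_frames: int = 20,
    frame_interval: float = 50.0,
) -> tuple[Trajectory, dict]:
    """Build a DNT-in-bilayer trajectory with known ground truth.

    The tube (default: six-duplex scaffold, d = 2.0 nm) is inserted at the
    requested tilt through a two-leaflet bilayer whose leaflet separation
    follows the thinning profile; lumen ions realise the requested
    cation:anion ratio by deterministic rounding; bulk electrolyte is
    neutral.  Frames add i.i.d. Gaussian jitter to the rigid template.
    """
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, float)
    centre = box / 2.0

    model = params.tube or build_hexagonal_scaffold()
    r_wall = model.outer_radius
    r_lumen = model.lumen_radius

    # --- tube particles, tilted about x and centred in the box
    tube_top, tube_frame = model_to_topology(model, box=box)
    tube_ref = tube_frame.positions - centre

    # --- lipid lattice outside the wall
    margin = r_wall + 0.3
    avail = box[0] * box[1] - np.pi * margin**2
    min_area = 0.55  # nm^2 per lipid, tighter packing than real PC is rejected
    if params.lipid_count * min_area > avail:
        raise ValueError(
            f"{params.lipid_count} lipids/leaflet exceed the available bilayer "
            f"area ({avail:.0f} nm^2)"
        )
    lipid_names, lipid_pos, lipid_mol = [], [], []
    mol_id = 1
    def _lattice_sites(n_side):
        xs = (np.arange(n_side) + 0.5) * box[0] / n_side - box[0] / 2
        ys = (np.arange(n_side) + 0.5) * box[1] / n_side - box[1] / 2
        return [(x, y) for x in xs for y in ys if np.hypot(x, y) >= margin]

    n_side = int(np.ceil(np.sqrt(params.lipid_count * box[0] * box[1] / avail)))
    sites = _lattice_sites(n_side)
    while len(sites) < params.lipid_count:
        n_side += 1
        sites = _lattice_sites(n_side)

    for sign in (+1, -1):
        placed = 0
        for x, y in sites:
            if placed >= params.lipid_count:
                break
            r = float(np.hypot(x, y))
            h_r = params.bilayer_thickness_h0 - params.thinning_amplitude * np.exp(
                -(r - r_wall) / params.thinning_decay
            )
            s_tgt = _order_target_at(params, r)
            for name, p in _lipid_template(rng, r, h_r, sign, s_tgt):
                lipid_names.append(name)
                lipid_pos.append(np.asarray(p, float) + [x, y, 0.0])
                lipid_mol.append(mol_id)
            mol_id += 1
            placed += 1

    # --- ions: lumen cylinder (tube-length extent) then neutral bulk
    ratio = params.lumen_cation_anion_ratio
    n_lumen = params.lumen_ion_count
    if np.isinf(ratio):
        n_cat = n_lumen
    else:
        n_cat = int(round(n_lumen * ratio / (1.0 + ratio)))
    n_an = n_lumen - n_cat
    half_len = model.length / 2.0

    def _lumen_points(k):
        rr = r_lumen * np.sqrt(rng.uniform(0, 1, k))
        th = rng.uniform(0, 2 * np.pi, k)
        zz = rng.uniform(-half_len, half_len, k)
        return np.column_stack([rr * np.cos(th), rr * np.sin(th), zz])

    def _bulk_points(k):
        pts = []
        while len(pts) < k:
            p = rng.uniform(-box / 2, box / 2, (k, 3))
            keep = np.hypot(p[:, 0], p[:, 1]) > r_wall
            pts.extend(p[keep])
        return np.asarray(pts[:k])

    ion_names, ion_pos = [], []
    for nm, pts in (("NA", _lumen_points(n_cat)), ("CL", _lumen_points(n_an)),
                    ("NA", _bulk_points(params.bulk_ion_pairs)),
                    ("CL", _bulk_points(params.bulk_ion_pairs))):
        for p in pts:
            ion_names.append(nm)
            ion_pos.append(p)

    water_pos = _bulk_points(params.water_count) if params.water_count else np.zeros((0, 3))

    # --- assemble topology
    assignments = []
    names, resnames, molecule, residue, helix, strand = [], [], [], [], [], []

    for i in range(tube_top.n_particles):
        assignments.append(RoleAssignment(tube_top.roles[i],
                                          bead_radius=tube_top.bead_radius[i]))
        names.append(tube_top.names[i])
        resnames.append("DNT")
        molecule.append(0)
        residue.append(tube_top.residue_index[i])
        helix.append(tube_top.helix_id[i])
        strand.append(tube_top.strand_id[i])

    # non-tube residue/molecule ids start after the tube's residue ids
    base = int(tube_top.residue_index.max()) + 1
    for nm, mid in zip(lipid_names, lipid_mol):
        role, tp = _LIPID_ROLE[nm]
        assignments.append(RoleAssignment(role, tail_position=tp, bead_radius=0.26))
        names.append(nm)
        resnames.append("POPC")
        molecule.append(base + mid)
        residue.append(base + mid)
        helix.append(-1)
        strand.append(-1)

    mid0 = base + mol_id
    for j, nm in enumerate(ion_names):
        role = Role.ION_NA if nm == "NA" else Role.ION_CL
        assignments.append(RoleAssignment(role, bead_radius=0.26))
        names.append(nm)
        resnames.append("ION")
        molecule.append(mid0 + j)
        residue.append(mid0 + j)
        helix.append(-1)
        strand.append(-1)
    mid0 += len(ion_names)
    for j in range(len(water_pos)):
        assignments.append(RoleAssignment(Role.WATER, bead_radius=0.26))
        names.append("W")
        resnames.append("W")
        molecule.append(mid0 + j)
        residue.append(mid0 + j)
        helix.append(-1)
        strand.append(-1)

    topology = ParticleTopology.from_assignments(
        assignments, molecule_id=molecule, residue_index=residue,
        names=names, resnames=resnames, helix_id=helix, strand_id=strand,
    )

    others = [np.asarray(lipid_pos).reshape(-1, 3),
              np.asarray(ion_pos).reshape(-1, 3), water_pos]
    template_other = np.vstack([a for a in others if len(a)]) if any(
        len(a) for a in others
    ) else np.zeros((0, 3))

    frames = []
    for i in range(n_frames):
        tilt = params.tilt_angle + (
            rng.normal(0.0, params.tilt_jitter_sd) if params.tilt_jitter_sd else 0.0
        )
        rad = np.deg2rad(tilt)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(rad), -np.sin(rad)],
                        [0, np.sin(rad), np.cos(rad)]])
        tube_pos = tube_ref @ rot.T
        pos = np.vstack([tube_pos, template_other]) + centre
        pos = pos + rng.normal(0.0, params.jitter_sd, pos.shape)
        frames.append(Frame(time=i * frame_interval, box=box.copy(), positions=pos))

    ground_truth = {
        "box": list(box),
        "bilayer_thickness_h0": params.bilayer_thickness_h0,
        "thinning_amplitude": params.thinning_amplitude,
        "thinning_decay": params.thinning_decay,
        "wall_radius": r_wall,
        "lumen_radius": r_lumen,
        "tube_length": model.length,
        "tilt_angle": params.tilt_angle,
        "tilt_jitter_sd": params.tilt_jitter_sd,
        "lumen_na": n_cat,
        "lumen_cl": n_an,
        "lumen_ratio": (n_cat / n_an) if n_an else float("inf"),
        "bulk_ion_pairs": params.bulk_ion_pairs,
        "order_param_target": (
            float(params.order_param_target)
            if np.isscalar(params.order_param_target)
            else list(params.order_param_target)
        ),
        "lipid_count_per_leaflet": params.lipid_count,
        "jitter_sd": params.jitter_sd,
        "seed": params.seed,
    }
    return Trajectory(topology=topology, frames=frames), ground_truth


def generate_smd_trace(
    params: SMDTraceParams,
    duration_us: float = 2.5,
    dt_ps: float = 100.0,
) -> tuple[ForceTrace, dict]:
    """Constant-velocity pulling trace: entry and exit Gaussian force bumps.

    The pulled-group COM advances at ``pull_velocity``; the applied force is
    an entry bump centred where the COM crosses the lower bilayer face, an
    exit bump at the upper face, a plateau and Gaussian noise.  The exit bump
    height 0 emulates a tube without a hydrophobic band, which leaves the
    bilayer without resistance.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, duration_us * 1e6 + 0.5 * dt_ps, dt_ps)
    v_nm_per_ps = params.pull_velocity * 1e-6
    com_z = params.start_z + v_nm_per_ps * t
    h = params.bilayer_half_thickness
    w = params.peak_width
    force = (
        params.plateau_force
        + params.entry_peak * np.exp(-0.5 * ((com_z + h) / w) ** 2)
        + params.exit_peak * np.exp(-0.5 * ((com_z - h) / w) ** 2)
    )
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, force.shape)
    trace = ForceTrace(time=t, force=force, com_z=com_z,
                       pull_velocity=params.pull_velocity)
    truth = {
        "entry_peak": params.entry_peak,
        "exit_peak": params.exit_peak,
        "entry_location_z": -h,
        "exit_location_z": h,
        "plateau_force": params.plateau_force,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
    }
    return trace, truth


def generate_displacement_trace(
    delta_z0: float,
    mode: str = "relax",
    relax_time_ns: float = 40.0,
    duration_ns: float = 200.0,
    dt_ps: float = 100.0,
    noise_sd: float = 0.02,
    drift_nm_per_ns: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """COM-displacement time series Δz(t) in nm.

    ``relax`` decays exponentially back to zero with time constant
    ``relax_time_ns / 3`` (so the trace reaches ~5 % of the initial offset at
    ``relax_time_ns``); ``exit`` drifts monotonically away with superimposed
    diffusion.  Returns ``(time_ps, dz_nm)``.
    """
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    if mode not in ("relax", "exit"):
        raise ValueError("mode must be 'relax' or 'exit'")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ns * 1000.0 + 0.5 * dt_ps, dt_ps)
    t_ns = t / 1000.0
    if mode == "relax":
        dz = delta_z0 * np.exp(-3.0 * t_ns / relax_time_ns)
    else:
        brownian = np.cumsum(rng.normal(0.0, noise_sd, t.shape))
        dz = delta_z0 + drift_nm_per_ns * t_ns + brownian
    if noise_sd > 0:
        dz = dz + rng.normal(0.0, noise_sd, t.shape)
    return t, dz


def generate_residence_trajectory(
    mean_lifetimes_ps: dict[tuple[str, str], float],
    n_frames: int = 400,
    frame_interval: float = 50.0,
    mean_gap_ps: float = 500.0,
    beads_per_kind: int = 10,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Contact-lifetime fixture for residence-time analysis.

    Two far-apart DNA anchor beads represent the minor- and major-groove
    surfaces; lipid beads of each requested kind alternate between a bound
    position (0.3 nm from their anchor) and an unbound one (3 nm away), with
    bound durations drawn from an exponential of the requested mean and
    unbound gaps from an exponential of ``mean_gap_ps``.  Keys of
    ``mean_lifetimes_ps`` are ``(MARTINI bead name, groove)`` pairs, e.g.
    ``("C2B", "minor")``.
    """
    rng = np.random.default_rng(seed)
    groove_x = {"minor": -2.0, "major": 2.0}
    box = np.array([20.0, 20.0, 20.0])

    assignments = [RoleAssignment(Role.DNA_BB, bead_radius=0.26)] * 2
    names = ["BB", "BB"]
    positions0 = [np.array([groove_x["minor"], 0.0, 0.0]),
                  np.array([groove_x["major"], 0.0, 0.0])]
    groove_labels = ["minor", "major"]

    schedules = []  # (particle_index, anchor_xyz, bound_mask per frame)
    times = np.arange(n_frames) * frame_interval
    span = times[-1] + frame_interval
    for (bead, groove), mean_life in mean_lifetimes_ps.items():
        role, tp = _LIPID_ROLE[bead]
        for b in range(beads_per_kind):
            assignments.append(RoleAssignment(role, tail_position=tp,
                                              bead_radius=0.26))
            names.append(bead)
            anchor = np.array([groove_x[groove], 0.3 * (b + 1), 0.0])
            bound = np.zeros(n_frames, bool)
            t_cursor, state = 0.0, bool(rng.integers(0, 2))
            while t_cursor < span:
                dur = rng.exponential(mean_life if state else mean_gap_ps)
                sel = (times >= t_cursor) & (times < t_cursor + dur)
                bound[sel] = state
                t_cursor += dur
                state = not state
            schedules.append((len(names) - 1, anchor, bound))
            positions0.append(anchor + [0.0, 0.0, 3.0])

    n = len(names)
    mol = list(range(n))
    topology = ParticleTopology.from_assignments(
        assignments, molecule_id=mol, residue_index=mol,
        names=names, resnames=["DNT", "DNT"] + ["POPC"] * (n - 2),
    )
    base = np.asarray(positions0) + box / 2.0
    frames = []
    for i in range(n_frames):
        pos = base.copy()
        for idx, anchor, bound in schedules:
            off = np.array([0.0, 0.0, 0.3 if bound[i] else 3.0])
            pos[idx] = anchor + off + box / 2.0
        frames.append(Frame(time=times[i], box=box.copy(), positions=pos))
    truth = {
        "mean_lifetimes_ps": {f"{k[0]}/{k[1]}": v
                              for k, v in mean_lifetimes_ps.items()},
        "mean_gap_ps": mean_gap_ps,
        "groove_labels": groove_labels,
        "seed": seed,
    }
    return Trajectory(topology=topology, frames=frames), truth
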