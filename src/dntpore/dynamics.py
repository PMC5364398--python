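"""Time-dependent analyses: lipid residence times, tube tilt, COM
displacement classification, SMD force barriers, partitioned r.m.s.d. and
membrane surface deformation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Frame, Trajectory, select
from .membrane import bilayer_midplane, minimum_image, pore_axis
from .roles import DNT_ROLES, LIPID_ROLES, Role
from .synth import ForceTrace

__all__ = [
    "ResidenceMap",
    "DisplacementTrace",
    "residence_times",
    "tilt_series",
    "com_displacement",
    "classify_displacement",
    "smd_barriers",
    "force_to_piconewtons",
    "piconewtons_to_force",
    "rmsd_partitioned",
    "membrane_deformation_track",
]

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# residence times

@dataclass
class ResidenceEvent:
    particle: int
    start_frame: int
    n_frames: int
    groove: str


@dataclass
class ResidenceMap:
    """Mean residence time (ps) and event count per (bead label, groove).

    Only "perturbed" lipid beads — those with at least one contact event in
    the window — contribute; beads that never touch the DNT are absent.
    """

    cutoff: float                       # nm
    frame_interval: float               # ps
    events: list = field(default_factory=list)

    def mean_residence(self) -> dict[tuple[str, str], tuple[float, int]]:
        acc: dict[tuple[str, str], list[int]] = {}
        for ev in self.events:
            acc.setdefault((ev.label, ev.groove), []).append(ev.n_frames)
        return {
            key: (float(np.mean(runs)) * self.frame_interval, len(runs))
            for key, runs in acc.items()
        }


@dataclass
class _LabelledEvent(ResidenceEvent):
    label: str = ""


def _runs(mask: np.ndarray, gap_tolerance: int):
    """Maximal runs of True, with gaps of <= gap_tolerance False frames merged."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def bead_label(topology, i: int) -> str:
    """Human-readable bead kind, e.g. the MARTINI name if available."""
    name = str(topology.names[i])
    return name if name else str(topology.roles[i].value)


def residence_times(
    traj: Trajectory,
    lipid_selection: Sequence[int],
    dna_selection: Sequence[int],
    cutoff: float = 0.5,
    gap_tolerance: int = 0,
    groove_labels: Optional[Sequence[str]] = None,
) -> ResidenceMap:
    """Contact residence times of lipid beads at the DNT surface.

    A contact event is a maximal run of frames in which a lipid bead's
    minimum distance to the DNA selection is ≤ ``cutoff`` (runs separated by
    ≤ ``gap_tolerance`` non-contact frames are merged).  Each event is
    labelled with the groove of the nearest DNA particle at its first frame;
    ``groove_labels`` is parallel to ``dna_selection`` ("minor"/"major"),
    defaulting to a single unlabelled category.
    """
    lipid_selection = np.asarray(lipid_selection, int)
    dna_selection = np.asarray(dna_selection, int)
    if len(lipid_selection) == 0 or len(dna_selection) == 0:
        raise ValueError("residence_times requires non-empty selections")
    if groove_labels is not None and len(groove_labels) != len(dna_selection):
        raise ValueError("groove_labels must be parallel to dna_selection")

    n_f = len(traj)
    min_dist = np.zeros((n_f, len(lipid_selection)))
    argmin = np.zeros((n_f, len(lipid_selection)), int)
    for fi, frame in enumerate(traj.frames):
        diff = (frame.positions[lipid_selection][:, None, :]
                - frame.positions[dna_selection][None, :, :])
        diff = minimum_image(diff, frame.box)
        dist = np.linalg.norm(diff, axis=-1)
        min_dist[fi] = dist.min(axis=1)
        argmin[fi] = dist.argmin(axis=1)

    interval = traj.frame_interval or 1.0
    rmap = ResidenceMap(cutoff=cutoff, frame_interval=interval)
    for li, pidx in enumerate(lipid_selection):
        contact = min_dist[:, li] <= cutoff
        for start, end in _runs(contact, gap_tolerance):
            groove = ("any" if groove_labels is None
                      else str(groove_labels[argmin[start, li]]))
            ev = _LabelledEvent(
                particle=int(pidx), start_frame=int(start),
                n_frames=int(end - start + 1), groove=groove,
                label=bead_label(traj.topology, pidx),
            )
            rmap.events.append(ev)
    return rmap


# ---------------------------------------------------------------------------
# tilt

def tilt_series(
    traj: Trajectory,
    tm_region: tuple[float, float] = (-2.0, 2.0),
    bins_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Acute angle (degrees) between the pore axis and the bilayer normal.

    Returns ``(angles_per_frame, histogram_counts, histogram_edges)``.
    The angle is invariant under flipping the axis direction.
    """
    angles = np.empty(len(traj))
    for fi, frame in enumerate(traj.frames):
        _, direction = pore_axis(frame, traj.topology, tm_region)
        cos = np.clip(abs(direction[2]), 0.0, 1.0)
        angles[fi] = np.degrees(np.arccos(cos))
    edges = np.arange(0.0, 90.0 + bins_deg, bins_deg)
    hist, _ = np.histogram(angles, bins=edges)
    return angles, hist, edges


# ---------------------------------------------------------------------------
# COM displacement

@dataclass
class DisplacementTrace:
    time: np.ndarray    # ps
    dz: np.ndarray      # nm, group COM minus bilayer COM along z
    classification: str  # relaxed | exited | undecided
    relaxation_time_ns: Optional[float] = None


def classify_displacement(
    time_ps: np.ndarray,
    dz: np.ndarray,
    tol_rel: float = 0.3,
    exit_threshold: float = 4.0,
) -> DisplacementTrace:
    """Classify a Δz(t) trace as relaxed, exited or undecided.

    ``relaxed``: |Δz| enters the ±``tol_rel`` band around zero and stays
    there to the end; the relaxation time is the first frame of the longest
    terminal in-band run.  ``exited``: |Δz| exceeds ``exit_threshold`` and
    never comes back below it.  Anything else is undecided.
    """
    time_ps = np.asarray(time_ps, float)
    dz = np.asarray(dz, float)
    in_band = np.abs(dz) <= tol_rel
    above = np.abs(dz) >= exit_threshold

    if in_band[-1]:
        # walk back through the terminal in-band run
        i = len(dz) - 1
        while i > 0 and in_band[i - 1]:
            i -= 1
        return DisplacementTrace(
            time=time_ps, dz=dz, classification="relaxed",
            relaxation_time_ns=float(time_ps[i] / 1000.0),
        )
    if above.any():
        first = int(np.argmax(above))
        if np.all(above[first:] | (np.abs(dz[first:]) >= exit_threshold * 0.8)):
            return DisplacementTrace(time=time_ps, dz=dz, classification="exited")
    return DisplacementTrace(time=time_ps, dz=dz, classification="undecided")


def com_displacement(
    traj: Trajectory,
    group_selection: Sequence[int],
    tol_rel: float = 0.3,
    exit_threshold: Optional[float] = None,
    bilayer_half_thickness: float = 2.0,
) -> DisplacementTrace:
    """Δz(t) of a group's COM relative to the bilayer COM, with classification.

    The default exit threshold is the bilayer half-thickness plus the group's
    axial half-extent plus 1 nm — far enough that the hydrophobic band is
    fully clear of the bilayer core.
    """
    group_selection = np.asarray(group_selection, int)
    if len(group_selection) == 0:
        raise ValueError("group selection is empty")
    dz = np.empty(len(traj))
    for fi, frame in enumerate(traj.frames):
        z0 = bilayer_midplane(frame, traj.topology)
        dz[fi] = frame.positions[group_selection, 2].mean() - z0
    if exit_threshold is None:
        gz = traj.frames[0].positions[group_selection, 2]
        half_extent = (gz.max() - gz.min()) / 2.0
        exit_threshold = bilayer_half_thickness + half_extent + 1.0
    return classify_displacement(traj.times, dz, tol_rel, exit_threshold)


# ---------------------------------------------------------------------------
# SMD barriers

@dataclass
class SMDBarriers:
    entry_barrier: float     # kJ mol^-1 nm^-1
    entry_location_z: float  # nm, COM-z at the entry peak
    exit_barrier: float
    exit_location_z: float
    smoothing_ns: float


def smd_barriers(
    trace: ForceTrace,
    bilayer_z: tuple[float, float] = (-2.0, 2.0),
    smoothing_ns: float = 5.0,
) -> SMDBarriers:
    """Entry and exit force barriers from a constant-velocity pulling trace.

    The force is smoothed with a centred running mean of ``smoothing_ns``.
    Windows are delimited by the pulled COM crossing the bilayer boundaries
    along the pulling direction: the entry window ends at the bilayer centre
    (it contains the full entry peak), the exit window starts at the far
    boundary, past the transmembrane plateau and clear of the entry peak's
    tail.  Within each window the barrier *location* is found on a 4x more
    heavily smoothed trace (nearly noise-free) and the barrier *height* is
    read from the lightly smoothed trace at that location — reading at a
    noise-independent location avoids the upward bias of picking the maximum
    of a noisy curve.
    """
    t, f, z = trace.time, np.asarray(trace.force, float), trace.com_z
    if len(t) < 3:
        raise ValueError("trace too short")
    dt = float(np.diff(t).mean())

    def running_mean(x, width_ns):
        w = max(1, int(round(width_ns * 1000.0 / dt)))
        if w <= 1:
            return x
        kernel = np.ones(w) / w
        out = np.convolve(x, kernel, mode="same")
        half = w // 2
        out[:half] = out[half]
        out[-half:] = out[-half - 1]
        return out

    f_light = running_mean(f, smoothing_ns)
    f_heavy = running_mean(f, 4.0 * smoothing_ns)

    direction = np.sign(z[-1] - z[0]) or 1.0
    lo, hi = sorted(direction * np.asarray(bilayer_z, float))
    u = direction * z
    mid = 0.5 * (lo + hi)
    if u[0] >= mid or u[-1] <= hi:
        raise ValueError(
            "pulled COM does not span the bilayer (no entry/exit windows)"
        )
    entry = u <= mid
    exit_ = u >= hi

    def pick(window):
        i = int(np.argmax(np.where(window, f_heavy, -np.inf)))
        return float(f_light[i]), float(z[i])

    entry_barrier, entry_z = pick(entry)
    exit_barrier, exit_z = pick(exit_)
    return SMDBarriers(
        entry_barrier=entry_barrier, entry_location_z=entry_z,
        exit_barrier=exit_barrier, exit_location_z=exit_z,
        smoothing_ns=smoothing_ns,
    )


def force_to_piconewtons(f_kj_mol_nm: float) -> float:
    """Convert a molar force to a single-molecule force in pN.

    1 kJ mol⁻¹ nm⁻¹ = 10³ J / (N_A · 10⁻⁹ m) ≈ 1.66054 pN.
    """
    return f_kj_mol_nm * 1e3 / (AVOGADRO * 1e-21)


def piconewtons_to_force(f_pn: float) -> float:
    """Inverse of :func:`force_to_piconewtons`."""
    return f_pn * (AVOGADRO * 1e-21) / 1e3


# ---------------------------------------------------------------------------
# partitioned r.m.s.d.

def rmsd_partitioned(
    traj: Trajectory,
    reference: Frame,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """r.m.s.d. of the DNT versus a reference, split TM / outside-the-membrane.

    Each frame is superposed onto the reference by a least-squares (Kabsch)
    fit over *all* DNA particles; the r.m.s.d. is then reported separately
    for particles inside and outside the reference TM z-window (relative to
    the reference bilayer midplane).  Returns ``(rmsd_tm, rmsd_outside)``.
    """
    top = traj.topology
    fit_set = select(top, roles=DNT_ROLES)
    if len(fit_set) < 3:
        raise ValueError("need at least 3 DNT particles for superposition")
    z0 = bilayer_midplane(reference, top)
    ref_z = reference.positions[fit_set, 2] - z0
    tm_mask = (ref_z >= tm_region[0]) & (ref_z <= tm_region[1])
    if not tm_mask.any() or tm_mask.all():
        raise ValueError("TM / outside partition is empty for this reference")

    ref = reference.positions[fit_set]
    ref_c = ref - ref.mean(axis=0)
    rmsd_tm = np.empty(len(traj))
    rmsd_out = np.empty(len(traj))
    for fi, frame in enumerate(traj.frames):
        mob = frame.positions[fit_set]
        mob_c = mob - mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob_c)
        aligned = rot.apply(mob_c)
        d2 = np.sum((aligned - ref_c) ** 2, axis=1)
        rmsd_tm[fi] = np.sqrt(d2[tm_mask].mean())
        rmsd_out[fi] = np.sqrt(d2[~tm_mask].mean())
    return rmsd_tm, rmsd_out


# ---------------------------------------------------------------------------
# membrane surface deformation

def membrane_deformation_track(
    traj: Trajectory,
    lateral_bin: float = 1.0,
    sample_every_ps: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-leaflet membrane surface curves in the xz plane over time.

    For each sampled frame and lateral x-bin, the curve is the COM z of the
    lipid particles in that bin, per leaflet (split at the phosphate median).
    Empty bins are NaN.  Returns ``(times_ps, x_centres, curves)`` with
    ``curves`` shaped (n_samples, 2, n_bins); leaflet 0 is the upper one.
    """
    lipid = select(traj.topology, roles=LIPID_ROLES)
    if len(lipid) == 0:
        raise ValueError("no lipid particles in topology")
    po4 = select(traj.topology, roles=Role.LIPID_PO4)
    box = traj.frames[0].box
    edges = np.arange(-box[0] / 2, box[0] / 2 + lateral_bin / 2, lateral_bin)
    centres = 0.5 * (edges[:-1] + edges[1:])

    times = traj.times
    if sample_every_ps is None:
        take = np.arange(len(traj))
    else:
        take, last = [], -np.inf
        for i, t in enumerate(times):
            if t - last >= sample_every_ps - 1e-9:
                take.append(i)
                last = t
        take = np.asarray(take, int)

    curves = np.full((len(take), 2, len(centres)), np.nan)
    for k, fi in enumerate(take):
        frame = traj.frames[fi]
        z_med = np.median(frame.positions[po4, 2]) if len(po4) else np.median(
            frame.positions[lipid, 2]
        )
        x = frame.positions[lipid, 0] - frame.box[0] / 2.0
        z = frame.positions[lipid, 2]
        upper = z > z_med
        bin_idx = np.digitize(x, edges) - 1
        ok = (bin_idx >= 0) & (bin_idx < len(centres))
        for leaflet, m_leaf in ((0, upper), (1, ~upper)):
            m = ok & m_leaf
            for b in np.unique(bin_idx[m]):
                curves[k, leaflet, b] = z[m & (bin_idx == b)].mean()
    return times[take], centres, curves
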