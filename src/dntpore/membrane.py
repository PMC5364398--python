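"""Bilayer structure around the nanopore: radial densities, thickness,
order parameters, radial distribution functions and lumen ion selectivity.

Conventions used throughout this module:

* z is the bilayer normal; z = 0 is the per-frame centre of mass of the
  lipid phosphates (recomputed every frame, so drifting inputs are fine).
* The pore axis is the principal axis of the transmembrane DNA particles,
  anchored at their centre of mass and oriented toward +z.
* Cylindrical shells are 0.1 nm wide and 4 nm long (approximately the
  membrane thickness) by default.
* Leaflets are split per frame by the phosphate median plane; flip-flop is
  not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .model import Frame, ParticleTopology, Trajectory, select
from .roles import DNT_ROLES, Role

__all__ = [
    "RadialProfile",
    "OrderParameterGrid",
    "RDFResult",
    "pore_axis",
    "bilayer_midplane",
    "radial_density",
    "thickness_profile",
    "fit_thinning",
    "order_parameter",
    "order_parameter_grid",
    "rdf",
    "ion_selectivity",
]


class DegenerateAxisError(ValueError):
    """The particle distribution has no unique long axis."""


def minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement(s)."""
    return vec - box * np.round(vec / box)


def bilayer_midplane(frame: Frame, topology: ParticleTopology) -> float:
    """z of the lipid-phosphate centre of mass.

    Membrane-free systems (e.g. the ideal tube alone) fall back to the DNT
    centre of mass so the axial origin still sits at the tube centre.
    """
    po4 = topology.role_mask(Role.LIPID_PO4)
    if po4.any():
        return float(frame.positions[po4, 2].mean())
    dnt = topology.role_mask(DNT_ROLES)
    if dnt.any():
        return float(frame.positions[dnt, 2].mean())
    return 0.0


def pore_axis(
    frame: Frame,
    topology: ParticleTopology,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Pore axis of the transmembrane DNT segment.

    Returns ``(anchor, direction)``: the COM of DNT particles whose z (relative
    to the bilayer midplane) lies in ``tm_region``, and the unit long/symmetry
    axis of the *whole* tube's gyration tensor, sign chosen toward +z.  The
    direction uses all DNT particles because restricting a tilted tube to a
    horizontal z-slab shears the selected segment and biases its tensor; the
    tube is rotationally symmetric about its axis, so the axis is the
    eigenvector whose eigenvalue is most separated from the (near-degenerate)
    other two — valid whether the tube is elongated or squat.  Raises
    :class:`DegenerateAxisError` when the spectrum offers no distinct axis
    (isotropic cloud) or the set is essentially planar.
    """
    z0 = bilayer_midplane(frame, topology)
    dnt = topology.role_mask(DNT_ROLES)
    z = frame.positions[:, 2] - z0
    sel = dnt & (z >= tm_region[0]) & (z <= tm_region[1])
    pts = frame.positions[sel]
    if len(pts) < 3:
        raise ValueError(
            f"pore axis needs >= 3 DNT particles in the TM region, got {len(pts)}"
        )
    com = pts.mean(axis=0)
    all_pts = frame.positions[dnt]
    centred = all_pts - all_pts.mean(axis=0)
    gyr = centred.T @ centred / len(all_pts)
    evals, evecs = np.linalg.eigh(gyr)  # ascending
    gap_low = evals[1] - evals[0]
    gap_high = evals[2] - evals[1]
    if max(gap_low, gap_high) < 0.05 * evals[2]:
        raise DegenerateAxisError(
            "particle set has no distinct symmetry axis (isotropic spectrum)"
        )
    if gap_high >= gap_low:
        direction = evecs[:, 2]
    else:
        if evals[0] < 1e-3 * evals[2]:
            raise DegenerateAxisError(
                "particle set is essentially planar; pore axis undefined"
            )
        direction = evecs[:, 0]
    if direction[2] < 0:
        direction = -direction
    return com, direction


def _axis_coords(frame, topology, indices, tm_region):
    """(radial, axial) coordinates of ``indices`` about the per-frame pore axis."""
    anchor, direction = pore_axis(frame, topology, tm_region)
    disp = minimum_image(frame.positions[indices] - anchor, frame.box)
    axial = disp @ direction
    radial = np.linalg.norm(disp - np.outer(axial, direction), axis=1)
    return radial, axial


@dataclass
class RadialProfile:
    """Per-role number densities (nm⁻³) and thickness (nm) in cylindrical shells."""

    shell_edges: np.ndarray                  # nm
    cylinder_half_length: float              # nm
    density_per_role: dict                   # role -> (n_shells,) densities
    mean_counts_per_role: dict               # role -> mean in-cylinder count
    thickness: Optional[np.ndarray] = None   # nm per shell, NaN = missing
    frames_used: int = 0

    @property
    def shell_centres(self) -> np.ndarray:
        return 0.5 * (self.shell_edges[:-1] + self.shell_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        e = self.shell_edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2) * 2 * self.cylinder_half_length


def radial_density(
    traj: Trajectory,
    roles: Iterable[Role],
    shell_width: float = 0.1,
    cylinder_half_length: float = 2.0,
    r_max: Optional[float] = None,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> RadialProfile:
    """Frame-averaged number densities versus radial distance from the pore axis.

    Particles enter the count when their axial coordinate lies within the
    cylinder; density in each shell is count / (π(r₂² − r₁²)·L) averaged over
    frames, so density·volume summed over shells equals the mean in-cylinder
    count per role exactly.
    """
    if len(traj) == 0:
        raise ValueError("trajectory has no frames")
    roles = list(roles)
    if r_max is None:
        r_max = float(min(traj.frames[0].box[:2]) / 2.0)
    edges = np.arange(0.0, r_max + shell_width / 2, shell_width)
    counts = {role: np.zeros(len(edges) - 1) for role in roles}
    for frame in traj.frames:
        for role in roles:
            idx = select(traj.topology, roles=role)
            if len(idx) == 0:
                continue
            radial, axial = _axis_coords(frame, traj.topology, idx, tm_region)
            inside = np.abs(axial) <= cylinder_half_length
            counts[role] += np.histogram(radial[inside], bins=edges)[0]
    volumes = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * 2 * cylinder_half_length
    n = len(traj)
    density = {role: counts[role] / n / volumes for role in roles}
    mean_counts = {role: counts[role].sum() / n for role in roles}
    return RadialProfile(
        shell_edges=edges,
        cylinder_half_length=cylinder_half_length,
        density_per_role=density,
        mean_counts_per_role=mean_counts,
        frames_used=n,
    )


def thickness_profile(
    traj: Trajectory,
    shell_width: float = 0.1,
    r_max: Optional[float] = None,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Bilayer thickness (upper- minus lower-leaflet mean phosphate z) per shell.

    Leaflets are split by the phosphate median plane each frame.  Shells where
    a frame has only one leaflet contribute nothing for that frame; shells
    never populated in both leaflets are NaN.  Returns ``(shell_centres,
    thickness)``.
    """
    po4 = select(traj.topology, roles=Role.LIPID_PO4)
    if len(po4) == 0:
        raise ValueError("no lipid phosphate particles in topology")
    if r_max is None:
        r_max = float(min(traj.frames[0].box[:2]) / 2.0)
    edges = np.arange(0.0, r_max + shell_width / 2, shell_width)
    nsh = len(edges) - 1
    thick_sum = np.zeros(nsh)
    thick_n = np.zeros(nsh, int)
    for frame in traj.frames:
        z = frame.positions[po4, 2]
        upper = z > np.median(z)
        if not upper.any() or upper.all():
            continue
        radial, _ = _axis_coords(frame, traj.topology, po4, tm_region)
        shell = np.digitize(radial, edges) - 1
        for s in range(nsh):
            m = shell == s
            if (m & upper).any() and (m & ~upper).any():
                thick_sum[s] += z[m & upper].mean() - z[m & ~upper].mean()
                thick_n[s] += 1
    thickness = np.where(thick_n > 0, thick_sum / np.maximum(thick_n, 1), np.nan)
    return 0.5 * (edges[:-1] + edges[1:]), thickness


def fit_thinning(
    r: np.ndarray,
    thickness: np.ndarray,
    r_wall: float,
) -> tuple[float, float, float]:
    """Fit h(r) = h0 − A·exp(−(r − r_wall)/λ) to a thickness profile.

    Returns ``(h0, A, lambda)``.  NaN shells are ignored; only r ≥ r_wall
    enters the fit.
    """
    m = np.isfinite(thickness) & (r >= r_wall)
    if m.sum() < 4:
        raise ValueError("too few populated shells to fit the thinning profile")

    def h(rr, h0, a, lam):
        return h0 - a * np.exp(-(rr - r_wall) / lam)

    h0_guess = np.nanmax(thickness[m])
    a_guess = max(h0_guess - np.nanmin(thickness[m]), 0.1)
    popt, _ = optimize.curve_fit(
        h, r[m], thickness[m], p0=[h0_guess, a_guess, 1.0],
        bounds=([0, 0, 1e-3], [np.inf, np.inf, np.inf]), maxfev=10000,
    )
    return tuple(float(x) for x in popt)


def order_parameter(vectors: np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """S = ⟨(3cos²θ − 1)/2⟩ for bond vectors against the bilayer normal."""
    v = np.asarray(vectors, float)
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    cos = (v @ n) / norms
    return float(np.mean(1.5 * cos**2 - 0.5))


@dataclass
class OrderParameterGrid:
    """Lipid-tail order parameter S per 1 × 1 nm² xy cell.

    Cells with fewer than ``min_samples`` bond samples are NaN (flagged
    missing, never zero-filled).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    S: np.ndarray       # (nx, ny), NaN = missing
    counts: np.ndarray  # (nx, ny) bond samples


def _tail_bonds(topology: ParticleTopology):
    """(i, j) particle pairs of consecutive tail beads within each chain."""
    pairs = []
    tails = {}
    for i, role in enumerate(topology.roles):
        if role in (Role.LIPID_TAIL_SN1, Role.LIPID_TAIL_SN2):
            key = (topology.molecule_id[i], role)
            tails.setdefault(key, []).append((topology.tail_position[i], i))
    for chain in tails.values():
        chain.sort()
        for (p0, i0), (p1, i1) in zip(chain[:-1], chain[1:]):
            if p1 == p0 + 1:
                pairs.append((i0, i1))
    return np.asarray(pairs, int).reshape(-1, 2)


def order_parameter_grid(
    traj: Trajectory,
    grid_cell: float = 1.0,
    min_samples: int = 10,
) -> OrderParameterGrid:
    """S on an xy grid; each lipid's bonds are binned at its phosphate xy."""
    top = traj.topology
    bonds = _tail_bonds(top)
    if len(bonds) == 0:
        raise ValueError("no consecutive tail beads with tail positions found")
    po4_of_mol = {}
    for i in select(top, roles=Role.LIPID_PO4):
        po4_of_mol[top.molecule_id[i]] = i
    bond_po4 = np.array([po4_of_mol.get(top.molecule_id[i], -1) for i, _ in bonds])
    valid = bond_po4 >= 0
    bonds, bond_po4 = bonds[valid], bond_po4[valid]

    box = traj.frames[0].box
    x_edges = np.arange(-box[0] / 2, box[0] / 2 + grid_cell / 2, grid_cell)
    y_edges = np.arange(-box[1] / 2, box[1] / 2 + grid_cell / 2, grid_cell)
    s_sum = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    n_sum = np.zeros_like(s_sum, dtype=int)
    for frame in traj.frames:
        centre = frame.box[:2] / 2.0
        vec = minimum_image(
            frame.positions[bonds[:, 1]] - frame.positions[bonds[:, 0]], frame.box
        )
        cos = vec[:, 2] / np.linalg.norm(vec, axis=1)
        s_val = 1.5 * cos**2 - 0.5
        xy = frame.positions[bond_po4][:, :2] - centre
        ix = np.digitize(xy[:, 0], x_edges) - 1
        iy = np.digitize(xy[:, 1], y_edges) - 1
        ok = (ix >= 0) & (ix < s_sum.shape[0]) & (iy >= 0) & (iy < s_sum.shape[1])
        np.add.at(s_sum, (ix[ok], iy[ok]), s_val[ok])
        np.add.at(n_sum, (ix[ok], iy[ok]), 1)
    S = np.where(n_sum >= min_samples, s_sum / np.maximum(n_sum, 1), np.nan)
    return OrderParameterGrid(x_edges=x_edges, y_edges=y_edges, S=S, counts=n_sum)


@dataclass
class RDFResult:
    r: np.ndarray                 # bin centres, nm
    g: np.ndarray                 # dimensionless
    normalization_density: float  # nm^-3 (mean density of set b)


def rdf(
    traj: Trajectory,
    set_a: Sequence[int],
    set_b: Sequence[int],
    bin_width: float = 0.02,
    r_max: float = 3.0,
) -> RDFResult:
    """Pair distribution g(r) between two particle selections.

    Standard minimum-image pair histogram normalized by the ideal-gas shell
    count at the box density of ``set_b``; self-pairs (shared indices) are
    excluded.  For homogeneous uncorrelated particles g(r) → 1.
    """
    set_a = np.asarray(set_a, int)
    set_b = np.asarray(set_b, int)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("rdf requires two non-empty selections")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist = np.zeros(len(edges) - 1)
    rho_sum = 0.0
    n_pairs_per_frame = 0.0
    for frame in traj.frames:
        diff = frame.positions[set_a][:, None, :] - frame.positions[set_b][None, :, :]
        diff = minimum_image(diff, frame.box)
        dist = np.linalg.norm(diff, axis=-1)
        self_pair = set_a[:, None] == set_b[None, :]
        dist = dist[~self_pair]
        n_pairs_per_frame = len(set_a) * len(set_b) - self_pair.sum()
        hist += np.histogram(dist, bins=edges)[0]
        rho_sum += len(set_b) / np.prod(frame.box)
    n_frames = len(traj)
    rho_b = rho_sum / n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_b_eff = n_pairs_per_frame / len(set_a)
    rho_eff = rho_b * n_b_eff / len(set_b)
    ideal = len(set_a) * rho_eff * shell_vol * n_frames
    g = np.where(ideal > 0, hist / np.maximum(ideal, 1e-300), 0.0)
    return RDFResult(r=0.5 * (edges[:-1] + edges[1:]), g=g,
                     normalization_density=rho_b)


@dataclass
class IonSelectivity:
    ratio: float               # time-averaged Na+ : Cl- in the lumen
    mean_na: float
    mean_cl: float
    ci_low: float              # 95 % CI on the ratio (binomial, pooled counts)
    ci_high: float


def ion_selectivity(
    traj: Trajectory,
    lumen_radius: float,
    lumen_half_length: float,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> IonSelectivity:
    """Cation:anion ratio inside the lumen cylinder, with a binomial 95 % CI.

    The lumen cylinder is centred on the per-frame pore axis; by convention
    its radius is the time-averaged minimum pore radius and its axial extent
    the full tube length.  A zero anion count yields an infinite ratio with
    the counts attached.
    """
    na = select(traj.topology, roles=Role.ION_NA)
    cl = select(traj.topology, roles=Role.ION_CL)
    if len(na) + len(cl) == 0:
        raise ValueError("no ions in topology")
    tot_na = tot_cl = 0
    for frame in traj.frames:
        for idx, is_na in ((na, True), (cl, False)):
            if len(idx) == 0:
                continue
            radial, axial = _axis_coords(frame, traj.topology, idx, tm_region)
            count = int(((radial <= lumen_radius)
                         & (np.abs(axial) <= lumen_half_length)).sum())
            if is_na:
                tot_na += count
            else:
                tot_cl += count
    n = len(traj)
    mean_na, mean_cl = tot_na / n, tot_cl / n
    total = tot_na + tot_cl
    if total == 0:
        raise ValueError("no ions found inside the lumen cylinder")
    ci = stats.binomtest(tot_na, total).proportion_ci(confidence_level=0.95)
    to_ratio = lambda p: p / (1.0 - p) if p < 1.0 else float("inf")
    ratio = mean_na / mean_cl if mean_cl > 0 else float("inf")
    return IonSelectivity(
        ratio=ratio, mean_na=mean_na, mean_cl=mean_cl,
        ci_low=to_ratio(ci.low), ci_high=to_ratio(ci.high),
    )
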