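"""Idealized six-duplex DNA-nanotube (DNT) geometry.

The tube is six parallel B-DNA duplexes whose axes sit on the vertices of a
regular hexagon (side = inter-helix spacing ``d``); each duplex is modelled
as one backbone pseudo-particle per nucleotide placed on an ideal helical
path (two strands, canonical rise 0.34 nm/bp, twist 34.3°/bp, backbone radius
1.0 nm).  Hydrophobic "bands" — rings of ethylated residues that anchor the
tube in the bilayer core — are flagged on the outward-facing backbone and can
be emitted as extra ETHYL particles.  An elastic-network specification
(harmonic pair restraints) can be derived from the built geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import Frame, ParticleTopology
from .roles import Role, RoleAssignment

__all__ = [
    "DNTModel",
    "ENMSpec",
    "build_hexagonal_scaffold",
    "place_hydrophobic_bands",
    "build_enm",
    "model_to_topology",
    "BAND_LAYOUTS",
    "SOFT_ENM_K",
    "STIFF_ENM_K",
    "CANONICAL_BDNA_RADIUS",
    "CANONICAL_RISE",
    "CANONICAL_TWIST",
]

CANONICAL_BDNA_RADIUS = 1.0   # nm, backbone radius of a B-DNA duplex
CANONICAL_RISE = 0.34         # nm per base pair
CANONICAL_TWIST = 34.3        # degrees per base pair
STRAND_PHASE_OFFSET = 144.0   # degrees between the two backbone strands

SOFT_ENM_K = 100.0            # kJ mol^-1 nm^-2
STIFF_ENM_K = 1000.0          # kJ mol^-1 nm^-2

BAND_LAYOUTS = ("7-band", "6-band", "1-ring", "2-adjacent", "2-distal",
                "full-coverage")


@dataclass
class DNTModel:
    """Built tube geometry plus per-residue annotation arrays."""

    n_helices: int
    spacing_d: float        # nm
    helix_radius: float     # nm
    length_bp: int
    rise_per_bp: float      # nm
    twist_per_bp: float     # degrees
    axis_points: np.ndarray     # (n_helices, 3) base point of each axis
    axis_direction: np.ndarray  # (3,) shared direction (axes are parallel)
    residue_positions: np.ndarray  # (N, 3) backbone positions, nm
    helix_id: np.ndarray        # (N,)
    strand_id: np.ndarray       # (N,) 0 or 1
    bp_index: np.ndarray        # (N,)
    groove_phase: np.ndarray    # (N,) degrees, residue phase about its axis
    band_id: np.ndarray = field(default=None)  # (N,) -1 = no band

    def __post_init__(self):
        if self.band_id is None:
            self.band_id = np.full(len(self.residue_positions), -1, int)

    @property
    def n_residues(self) -> int:
        return len(self.residue_positions)

    @property
    def length(self) -> float:
        """Axial tube length in nm."""
        return (self.length_bp - 1) * self.rise_per_bp

    @property
    def surface_gap(self) -> float:
        """Gap between adjacent duplex surfaces; 0 means touching."""
        return self.spacing_d - 2 * self.helix_radius

    @property
    def lumen_radius(self) -> float:
        """Radius of the largest axis-centred sphere clearing all duplexes."""
        return self.spacing_d - self.helix_radius

    @property
    def outer_radius(self) -> float:
        return self.spacing_d + self.helix_radius

    def band_mask(self) -> np.ndarray:
        return self.band_id >= 0

    def band_z_extent(self) -> Optional[tuple[float, float]]:
        m = self.band_mask()
        if not m.any():
            return None
        z = self.residue_positions[m] @ self.axis_direction
        return float(z.min()), float(z.max())

    def outer_surface_mask(self) -> np.ndarray:
        """Residues whose backbone faces away from the tube centre."""
        xy = self.residue_positions[:, :2]
        axis_xy = self.axis_points[self.helix_id][:, :2]
        return np.linalg.norm(xy, axis=1) > np.linalg.norm(axis_xy, axis=1)

    def groove_of_phase(self, helix: int, bp: int, psi_deg: float) -> str:
        """Classify an angular direction ``psi`` about a duplex axis as facing
        the minor or major groove of base pair ``bp``.

        The two strands are offset by 144° across the minor groove; the minor
        groove window is ±60° about the bisector of that gap, the major groove
        is the remainder.
        """
        sel = (self.helix_id == helix) & (self.bp_index == bp) & (self.strand_id == 0)
        if not sel.any():
            raise ValueError(f"no residue for helix {helix}, bp {bp}")
        phi0 = float(self.groove_phase[sel][0])
        bisector = phi0 + STRAND_PHASE_OFFSET / 2.0
        delta = (psi_deg - bisector + 180.0) % 360.0 - 180.0
        return "minor" if abs(delta) <= 60.0 else "major"


@dataclass
class ENMSpec:
    """Elastic-network restraints derived from a built model."""

    bonds: np.ndarray        # (M, 2) residue index pairs
    rest_lengths: np.ndarray  # (M,) nm, equal to build-time distances
    force_constants: np.ndarray  # (M,) kJ mol^-1 nm^-2
    stiffness_mode: str


def _hexagon_vertices(n: int, side: float) -> np.ndarray:
    """First ``n`` vertices of a regular hexagon of the given side length.

    For a regular hexagon the circumradius equals the side, so vertices sit
    at distance ``side`` from the origin at 60° steps.
    """
    ang = np.deg2rad(60.0 * np.arange(n))
    return np.column_stack([side * np.cos(ang), side * np.sin(ang), np.zeros(n)])


def build_hexagonal_scaffold(
    n_helices: int = 6,
    spacing_d: float = 2.0,
    helix_radius: float = CANONICAL_BDNA_RADIUS,
    length_bp: int = 30,
    rise_per_bp: float = CANONICAL_RISE,
    twist_per_bp: float = CANONICAL_TWIST,
) -> DNTModel:
    """Place ``n_helices`` ideal duplexes on a hexagonal grid of side ``spacing_d``.

    Residue backbone positions follow ideal helical paths about each (parallel,
    z-aligned) axis; the tube is centred axially on z = 0.  Each duplex's
    inward-facing phase is rotated to face the tube centre so the lumen wall
    is rotationally symmetric.
    """
    if not 1 <= n_helices <= 6:
        raise ValueError("n_helices must be in 1..6")
    for name, v in [("spacing_d", spacing_d), ("helix_radius", helix_radius),
                    ("length_bp", length_bp), ("rise_per_bp", rise_per_bp),
                    ("twist_per_bp", twist_per_bp)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    if n_helices == 1:
        axes = np.zeros((1, 3))
    else:
        axes = _hexagon_vertices(n_helices, spacing_d)
    gap = spacing_d - 2 * helix_radius
    if n_helices > 1 and gap < -1e-9:
        raise ValueError(
            f"duplexes overlap: spacing {spacing_d} < 2 x radius {helix_radius}"
        )

    positions, hel, strand, bp, phase = [], [], [], [], []
    for h in range(n_helices):
        # phase origin points from the axis toward the tube centre
        centre_dir = -axes[h][:2]
        phase0 = 0.0 if np.allclose(centre_dir, 0) else np.degrees(
            np.arctan2(centre_dir[1], centre_dir[0])
        )
        for j in range(length_bp):
            z = (j - (length_bp - 1) / 2.0) * rise_per_bp
            for s in (0, 1):
                phi = phase0 + j * twist_per_bp + s * STRAND_PHASE_OFFSET
                rad = np.deg2rad(phi)
                positions.append(axes[h] + [helix_radius * np.cos(rad),
                                            helix_radius * np.sin(rad), z])
                hel.append(h)
                strand.append(s)
                bp.append(j)
                phase.append(phi % 360.0)

    return DNTModel(
        n_helices=n_helices,
        spacing_d=spacing_d,
        helix_radius=helix_radius,
        length_bp=length_bp,
        rise_per_bp=rise_per_bp,
        twist_per_bp=twist_per_bp,
        axis_points=axes,
        axis_direction=np.array([0.0, 0.0, 1.0]),
        residue_positions=np.asarray(positions),
        helix_id=np.asarray(hel, int),
        strand_id=np.asarray(strand, int),
        bp_index=np.asarray(bp, int),
        groove_phase=np.asarray(phase),
    )


def _ring_centres(layout: str, length_bp: int, ring_gap_bp: int) -> list[int]:
    mid = (length_bp - 1) // 2
    if layout == "1-ring":
        return [mid]
    if layout == "2-adjacent":
        return [mid - ring_gap_bp // 2, mid + (ring_gap_bp + 1) // 2]
    if layout == "2-distal":
        half_span = 3 * ring_gap_bp
        return [mid - half_span, mid + half_span]
    n = 7 if layout == "7-band" else 6
    offsets = (np.arange(n) - (n - 1) / 2.0) * ring_gap_bp
    return [int(round(mid + o)) for o in offsets]


def place_hydrophobic_bands(
    model: DNTModel,
    band_spec: str | Sequence[int],
    ring_gap_bp: int = 3,
    ring_width_bp: int = 1,
) -> DNTModel:
    """Flag hydrophobic-band residues on the tube's outer surface.

    ``band_spec`` is a named layout (single ring, two adjacent or two distal
    rings, six or seven evenly spaced rings, or full surface coverage) or an
    explicit residue-index list.  Rings are contiguous axial windows of
    ``ring_width_bp`` base pairs centred at the tube mid-height; layouts with
    several rings space them ``ring_gap_bp`` base pairs apart, and the
    two-distal layout splits symmetrically about mid-height.
    """
    band_id = np.full(model.n_residues, -1, int)
    if not isinstance(band_spec, str):
        idx = np.asarray(list(band_spec), int)
        if len(idx) and (idx.min() < 0 or idx.max() >= model.n_residues):
            raise ValueError("explicit band residue index out of range")
        band_id[idx] = 0
    else:
        if band_spec not in BAND_LAYOUTS:
            raise ValueError(
                f"unknown band layout {band_spec!r}; known layouts: "
                f"{', '.join(BAND_LAYOUTS)}"
            )
        outer = model.outer_surface_mask()
        if band_spec == "full-coverage":
            band_id[outer] = 0
        else:
            centres = _ring_centres(band_spec, model.length_bp, ring_gap_bp)
            for b, c in enumerate(centres):
                if not 0 <= c < model.length_bp:
                    raise ValueError(
                        f"band layout {band_spec!r} does not fit a "
                        f"{model.length_bp}-bp tube"
                    )
                lo = c - (ring_width_bp - 1) // 2
                hi = lo + ring_width_bp - 1
                in_ring = (model.bp_index >= lo) & (model.bp_index <= hi) & outer
                band_id[in_ring] = b
    out = DNTModel(**{**model.__dict__})
    out.band_id = band_id
    return out


def build_enm(
    model: DNTModel,
    stiffness_mode: str = "stiff",
    cutoff: float = 1.2,
    junction_pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> ENMSpec:
    """Harmonic pair restraints between residues within ``cutoff`` of each other.

    Bonds are generated within each duplex only; inter-helix junction
    restraints, where wanted, are passed explicitly as residue-index pairs
    (the strand routing at the junctions is not modelled as sequence).  Soft
    mode assigns k = 100 kJ mol⁻¹ nm⁻²; rest lengths equal build-time
    distances exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if stiffness_mode not in ("stiff", "soft"):
        raise ValueError("stiffness_mode must be 'stiff' or 'soft'")
    tree = cKDTree(model.residue_positions)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), int).reshape(-1, 2)
    if len(pairs):
        same_helix = model.helix_id[pairs[:, 0]] == model.helix_id[pairs[:, 1]]
        pairs = pairs[same_helix]
    if junction_pairs:
        pairs = np.vstack([pairs, np.asarray(junction_pairs, int)])
    rest = np.linalg.norm(
        model.residue_positions[pairs[:, 0]] - model.residue_positions[pairs[:, 1]],
        axis=1,
    ) if len(pairs) else np.zeros(0)
    k = SOFT_ENM_K if stiffness_mode == "soft" else STIFF_ENM_K
    return ENMSpec(
        bonds=pairs,
        rest_lengths=rest,
        force_constants=np.full(len(pairs), k),
        stiffness_mode=stiffness_mode,
    )


ETHYL_OFFSET = 0.2  # nm, radial offset of an ethyl bead from its backbone residue


def model_to_topology(
    model: DNTModel,
    bead_radius: float = 0.26,
    ethyl_radius: float = 0.23,
    box: Sequence[float] = (18.0, 18.0, 25.0),
) -> tuple[ParticleTopology, Frame]:
    """Emit the built model as particles: one DNA_BB bead per residue plus one
    ETHYL bead, offset radially outward, per band-flagged residue."""
    n = model.n_residues
    band = model.band_mask()
    assignments = [RoleAssignment(Role.DNA_BB, bead_radius=bead_radius)] * n
    names = ["BB"] * n
    positions = [model.residue_positions]
    helix = list(model.helix_id)
    strand = list(model.strand_id)
    resid = list(range(n))
    mol = [0] * n

    eth_idx = np.nonzero(band)[0]
    if len(eth_idx):
        axis_xy = model.axis_points[model.helix_id[eth_idx]][:, :2]
        xy = model.residue_positions[eth_idx, :2]
        outward = xy - axis_xy
        norm = np.linalg.norm(outward, axis=1, keepdims=True)
        outward = np.where(norm > 0, outward / norm, 0.0)
        eth_pos = model.residue_positions[eth_idx].copy()
        eth_pos[:, :2] += ETHYL_OFFSET * outward
        positions.append(eth_pos)
        assignments = assignments + [
            RoleAssignment(Role.ETHYL, bead_radius=ethyl_radius)
        ] * len(eth_idx)
        names += ["ET"] * len(eth_idx)
        helix += list(model.helix_id[eth_idx])
        strand += list(model.strand_id[eth_idx])
        resid += list(eth_idx)
        mol += [0] * len(eth_idx)

    pos = np.vstack(positions)
    box = np.asarray(box, float)
    top = ParticleTopology.from_assignments(
        assignments,
        molecule_id=mol,
        residue_index=resid,
        names=names,
        resnames=["DNT"] * len(names),
        helix_id=helix,
        strand_id=strand,
    )
    frame = Frame(time=0.0, box=box, positions=pos + box / 2.0 * [1, 1, 0])
    # recentre laterally in the box, keep the tube centred on z = box_z/2
    frame.positions[:, 2] += box[2] / 2.0
    return top, frame


def mean_nearest_neighbour_axis_distance(model: DNTModel) -> float:
    """Mean distance from each helix axis to its nearest neighbouring axis."""
    if model.n_helices < 2:
        raise ValueError("need at least two helices")
    d = np.linalg.norm(
        model.axis_points[:, None, :] - model.axis_points[None, :, :], axis=-1
    )
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())
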