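"""Largest-inscribed-sphere pore-radius profiling and conductance prediction.

At each position z along the pore axis the profiler finds the largest sphere,
centred in the slice plane, that overlaps no pore-forming particle: it
maximises ``min_i(|c - p_i| - r_i)`` over the in-plane centre c by
simulated-annealing Monte Carlo.  Water and ions are excluded by default;
each remaining particle contributes its probe (bead) radius.  Slice centres
are chained along z so the centre path stays continuous, with periodic
independent restarts to escape side channels.

Conductance is predicted from a radius profile with the ohmic pore model
g = πR²/(ρL) (uniform-cylinder mode) or its series-resistor generalisation
1/g = (ρ/π)·Σ Δz/R(z)².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .model import Trajectory, select
from .membrane import bilayer_midplane, pore_axis, minimum_image
from .roles import Role

__all__ = [
    "PoreProfile",
    "ConductanceEstimate",
    "pore_radius_slice",
    "pore_profile_over_time",
    "conductance_estimate",
    "conductance_ratio",
    "RESISTIVITY_OHM_CM",
]

#: Electrolyte resistivities (Ω·cm) used for conductance prediction; the
#: conductivity of a dilute electrolyte is roughly proportional to its
#: concentration, hence ρ(0.3 M) ≈ 3 × ρ(1.0 M).
RESISTIVITY_OHM_CM = {
    "KCl_1.0M": 8.9,
    "KCl_0.3M": 27.4,
    "NaCl_0.15M": 62.0,
}

_OHM_CM_TO_OHM_NM = 1e7
_DEFAULT_EXCLUDE = frozenset({Role.WATER, Role.ION_NA, Role.ION_CL})


class _ClearanceField:
    """min over particles of (distance from a point − particle radius).

    Small particle sets are evaluated directly; large ones through a k-d
    tree: the nearest particle bounds the clearance, and only particles
    within that bound + max radius can beat it.
    """

    def __init__(self, pos: np.ndarray, radii: np.ndarray):
        self.pos = pos
        self.radii = radii
        self.r_max = float(radii.max()) if len(radii) else 0.0
        if len(pos) > 256:
            from scipy.spatial import cKDTree

            self.tree = cKDTree(pos)
        else:
            self.tree = None

    def at(self, centre_xy, z) -> float:
        c = np.array([centre_xy[0], centre_xy[1], z])
        if self.tree is None:
            return float((np.linalg.norm(self.pos - c, axis=1) - self.radii).min())
        d0, i0 = self.tree.query(c)
        best = d0 - self.radii[i0]
        idx = self.tree.query_ball_point(c, best + self.r_max + 1e-12)
        if idx:
            idx = np.asarray(idx)
            d = np.linalg.norm(self.pos[idx] - c, axis=1) - self.radii[idx]
            best = min(best, float(d.min()))
        return float(best)


def pore_radius_slice(
    positions: np.ndarray,
    radii: np.ndarray,
    z: float,
    centre0: tuple[float, float] = (0.0, 0.0),
    r_cap: float = 5.0,
    n_moves: int = 1000,
    step_start: float = 0.1,
    step_end: float = 0.01,
    seed: int = 0,
    search_extent: Optional[float] = None,
) -> tuple[float, tuple[float, float], bool]:
    """Largest-inscribed-sphere radius in the plane at height ``z``.

    Maximises the clearance function by Metropolis annealing in xy starting
    from ``centre0``, with the proposal step cooling geometrically from
    ``step_start`` to ``step_end`` over ``n_moves`` moves, followed by a
    deterministic pattern-search polish.  With ``search_extent`` set, a
    coarse 0.1 nm grid over ``centre0 ± search_extent`` seeds the annealer
    at the best coarse cell first, making the search global over that square.
    The radius is capped at ``r_cap``; a slice with no particle within reach
    is flagged open.  Returns ``(radius, centre_xy, open_flag)``.
    """
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    near = np.abs(positions[:, 2] - z) <= r_cap + (radii.max() if len(radii) else 0.0)
    pos = positions[near]
    rad = radii[near]
    if len(pos) == 0:
        return r_cap, tuple(centre0), True

    field = _ClearanceField(pos, rad)
    rng = np.random.default_rng(seed)
    c = np.asarray(centre0, float)
    extra_starts: list[np.ndarray] = []
    if search_extent is not None:
        # coarse global scan; the best few well-separated cells become
        # candidate basins (near-tied basins are resolved by local polish)
        g = np.arange(-search_extent, search_extent + 0.05, 0.1)
        gx, gy = np.meshgrid(c[0] + g, c[1] + g)
        cand = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
        clear = (np.linalg.norm(cand[:, None, :] - pos[None, :, :], axis=-1)
                 - rad).min(axis=1)
        order = np.argsort(clear)[::-1]
        picked: list[np.ndarray] = []
        for i in order:
            p = cand[i, :2]
            if all(np.linalg.norm(p - q) > 0.25 for q in picked):
                picked.append(p.copy())
            if len(picked) >= 5:
                break
        c = picked[0].copy()
        extra_starts = picked[1:]
    best_c = c.copy()
    f_c = field.at(c, z)
    f_best = f_c
    decay = (step_end / step_start) ** (1.0 / max(n_moves - 1, 1))
    step = step_start
    for _ in range(n_moves):
        trial = c + rng.normal(0.0, step, 2)
        f_t = field.at(trial, z)
        # temperature tied to the step size: accept mild downhill moves early
        temp = 0.5 * step
        if f_t >= f_c or rng.random() < np.exp((f_t - f_c) / temp):
            c, f_c = trial, f_t
            if f_c > f_best:
                best_c, f_best = c.copy(), f_c
        step *= decay
    # deterministic pattern-search polish with shrinking steps
    dirs = np.array([[1, 0], [-1, 0], [0, 1], [0, -1],
                     [1, 1], [1, -1], [-1, 1], [-1, -1]], float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    def _polish(c0, f0):
        cc, ff = np.asarray(c0, float).copy(), f0
        h = 0.05
        budget = 400  # evaluations; also bails out once the cap is reached
        while h >= 0.002 and ff < r_cap and budget > 0:
            moved = False
            for d in dirs:
                trial = cc + h * d
                f_t = field.at(trial, z)
                budget -= 1
                if f_t > ff:
                    cc, ff = trial, f_t
                    moved = True
            if not moved:
                h /= 2.0
        return cc, ff

    best_c, f_best = _polish(best_c, f_best)
    for start in extra_starts:
        cc, ff = _polish(start, field.at(start, z))
        if ff > f_best:
            best_c, f_best = cc, ff
    radius = min(max(f_best, 0.0), r_cap)
    return radius, (float(best_c[0]), float(best_c[1])), radius >= r_cap


@dataclass
class PoreProfile:
    """Per-frame and time-averaged pore radius along the axis."""

    z_grid: np.ndarray            # nm, in axis coordinates
    radius_per_frame: np.ndarray  # (n_frames, n_z), nm
    open_flags: np.ndarray        # (n_frames, n_z) bool, True = hit r_cap
    mean_radius: np.ndarray       # (n_z,), over valid (non-open) frames
    sd_radius: np.ndarray         # (n_z,)
    centre_path: np.ndarray       # (n_frames, n_z, 2)
    r_cap: float

    def mean_over(self, z_range: tuple[float, float]) -> float:
        """Mean of the time-averaged radius over an axial window."""
        m = (self.z_grid >= z_range[0]) & (self.z_grid <= z_range[1])
        vals = self.mean_radius[m]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError("no valid slices in the requested z range")
        return float(vals.mean())


def pore_profile_over_time(
    traj: Trajectory,
    z_range: tuple[float, float] = (-5.0, 5.0),
    dz: float = 0.2,
    exclude_roles: Iterable[Role] = _DEFAULT_EXCLUDE,
    extra_probe: float = 0.0,
    r_cap: Optional[float] = None,
    n_moves: int = 1000,
    restart_every: int = 10,
    seed: int = 0,
    tm_region: tuple[float, float] = (-2.0, 2.0),
) -> PoreProfile:
    """Pore-radius profile for every frame, plus mean ± SD over frames.

    Particle positions are transformed into axis coordinates per frame (the
    pore axis becomes z, the bilayer midplane z = 0).  Slices are optimized
    sequentially, each seeded from the previous slice's centre; every
    ``restart_every`` slices an independent restart from the axis competes
    with the chained seed.  ``extra_probe`` is added to every bead radius.
    """
    exclude_roles = set(exclude_roles)
    top = traj.topology
    keep = ~top.role_mask(exclude_roles)
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        raise ValueError("no particles left after role exclusion")
    radii = top.bead_radius[idx] + extra_probe
    if np.any(~np.isfinite(radii)) or np.any(radii < 0):
        raise ValueError("profiled particles need finite non-negative bead radii")

    if r_cap is None:
        r_cap = float(min(traj.frames[0].box[:2]) / 2.0)
    z_grid = np.arange(z_range[0], z_range[1] + dz / 2, dz)
    n_f, n_z = len(traj), len(z_grid)
    rad_mat = np.zeros((n_f, n_z))
    open_mat = np.zeros((n_f, n_z), bool)
    centres = np.zeros((n_f, n_z, 2))

    for fi, frame in enumerate(traj.frames):
        anchor, direction = pore_axis(frame, top, tm_region)
        z0 = bilayer_midplane(frame, top)
        # orthonormal frame with the pore axis as its z
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(direction, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        basis = np.column_stack([e1, e2, direction])
        disp = minimum_image(frame.positions[idx] - anchor, frame.box)
        local = disp @ basis
        # axial origin where the bilayer midplane crosses the axis
        local[:, 2] += (anchor[2] - z0) / direction[2]

        centre = (0.0, 0.0)
        for zi, z in enumerate(z_grid):
            slice_seed = (seed * 1_000_003 + fi * 8191 + zi) % (2**31)
            r1, c1, o1 = pore_radius_slice(
                local, radii, z, centre0=centre, r_cap=r_cap,
                n_moves=n_moves, seed=slice_seed,
            )
            if zi % restart_every == 0 and centre != (0.0, 0.0):
                r2, c2, o2 = pore_radius_slice(
                    local, radii, z, centre0=(0.0, 0.0), r_cap=r_cap,
                    n_moves=n_moves, seed=slice_seed + 1,
                )
                if r2 > r1:
                    r1, c1, o1 = r2, c2, o2
            rad_mat[fi, zi] = r1
            open_mat[fi, zi] = o1
            centres[fi, zi] = c1
            centre = c1

    valid = ~open_mat
    with np.errstate(invalid="ignore"):
        mean = np.where(valid.any(axis=0),
                        np.nanmean(np.where(valid, rad_mat, np.nan), axis=0),
                        np.nan)
        sd = np.where(valid.sum(axis=0) > 1,
                      np.nanstd(np.where(valid, rad_mat, np.nan), axis=0),
                      0.0)
    return PoreProfile(
        z_grid=z_grid, radius_per_frame=rad_mat, open_flags=open_mat,
        mean_radius=mean, sd_radius=sd, centre_path=centres, r_cap=r_cap,
    )


@dataclass
class ConductanceEstimate:
    g_nS: float
    resistivity_ohm_cm: float
    length: float          # nm
    mode: str
    mean_radius: float     # nm (uniform mode); NaN for series mode
    closed_at: Optional[float] = None  # z of first zero-radius slice


def conductance_estimate(
    profile: PoreProfile,
    resistivity_ohm_cm: float,
    mode: str = "series_integral",
    z_range: Optional[tuple[float, float]] = None,
) -> ConductanceEstimate:
    """Ohmic conductance of the profiled pore.

    ``uniform`` treats the pore as a cylinder of the mean radius R over the
    window (g = πR²/ρL); ``series_integral`` sums slice resistances
    (1/g = ρ/π · Σ Δz/R(z)²).  Slices that hit the radius cap (open bulk)
    are excluded; a zero-radius slice closes the pore in series mode.
    """
    if mode not in ("uniform", "series_integral"):
        raise ValueError("mode must be 'uniform' or 'series_integral'")
    z = profile.z_grid
    r = profile.mean_radius
    m = np.isfinite(r)
    if z_range is not None:
        m &= (z >= z_range[0]) & (z <= z_range[1])
    if m.sum() < 2:
        raise ValueError("fewer than two valid slices in the requested window")
    z_sel, r_sel = z[m], r[m]
    length = z_sel[-1] - z_sel[0]
    rho_nm = resistivity_ohm_cm * _OHM_CM_TO_OHM_NM

    if np.any(r_sel <= 0):
        return ConductanceEstimate(
            g_nS=0.0, resistivity_ohm_cm=resistivity_ohm_cm, length=float(length),
            mode=mode, mean_radius=float(np.mean(r_sel)),
            closed_at=float(z_sel[np.argmax(r_sel <= 0)]),
        )
    if mode == "uniform":
        R = float(r_sel.mean())
        g = np.pi * R**2 / (rho_nm * length)
        mean_r = R
    else:
        # trapezoidal series-resistor integral: 1/g = (rho/pi) int dz / R(z)^2
        inv_g = rho_nm / np.pi * np.trapezoid(1.0 / r_sel**2, z_sel)
        g = 1.0 / inv_g
        mean_r = float(r_sel.mean())
    return ConductanceEstimate(
        g_nS=float(g * 1e9), resistivity_ohm_cm=resistivity_ohm_cm,
        length=float(length), mode=mode, mean_radius=mean_r,
    )


def conductance_ratio(
    profile_low: PoreProfile,
    profile_high: PoreProfile,
    rho_low_ohm_cm: float,
    rho_high_ohm_cm: float,
    mode: str = "series_integral",
    z_range: Optional[tuple[float, float]] = None,
) -> float:
    """g(high-salt profile) / g(low-salt profile) via :func:`conductance_estimate`."""
    g_low = conductance_estimate(profile_low, rho_low_ohm_cm, mode, z_range).g_nS
    g_high = conductance_estimate(profile_high, rho_high_ohm_cm, mode, z_range).g_nS
    if g_low == 0:
        raise ZeroDivisionError("low-salt profile is closed (g = 0)")
    return g_high / g_low
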