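"""Radial densities, thickness, order parameters, RDF and ion selectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from dntpore.membrane import (DegenerateAxisError, fit_thinning,
                              ion_selectivity, order_parameter,
                              order_parameter_grid, pore_axis, radial_density,
                              rdf, thickness_profile)
from dntpore.model import Frame, ParticleTopology, Trajectory, select
from dntpore.roles import Role, RoleAssignment
from dntpore.synth import MembraneSystemParams, generate_membrane_system


def _point_cloud_traj(points, role=Role.WATER, box=(10.0, 10.0, 10.0),
                      extra_dnt_axis=True, n_frames=1, radius=0.26):
    """Trajectory from raw points, optionally with a thin DNT rod on z to
    define the pore axis."""
    points = np.asarray(points, float)
    box = np.asarray(box, float)
    pts = points + box / 2.0
    roles = [role] * len(points)
    if extra_dnt_axis:
        rod = np.array([[0.05 * np.cos(k), 0.05 * np.sin(k), zz]
                        for k, zz in zip(np.linspace(0, 6, 13),
                                         np.linspace(-3, 3, 13))])
        pts = np.vstack([pts, rod + box / 2.0])
        roles += [Role.DNA_BB] * len(rod)
    n = len(pts)
    top = ParticleTopology.from_assignments(
        [RoleAssignment(r, bead_radius=radius) for r in roles],
        molecule_id=np.arange(n), residue_index=np.arange(n),
        names=[r.value[:4] for r in roles], resnames=["X"] * n,
    )
    frames = [Frame(time=50.0 * i, box=box.copy(), positions=pts.copy())
              for i in range(n_frames)]
    return Trajectory(top, frames)


class TestPoreAxis:
    def test_untilted_tube_axis_is_z(self, membrane_system):
        traj, _ = membrane_system
        _, direction = pore_axis(traj.frames[0], traj.topology)
        assert abs(direction[2]) > 1 - 1e-3

    def test_constructed_tilt_recovered(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      tilt_angle=10.0, jitter_sd=0.01, seed=5)
        traj, _ = generate_membrane_system(params, n_frames=1)
        _, direction = pore_axis(traj.frames[0], traj.topology)
        angle = np.degrees(np.arccos(abs(direction[2])))
        assert angle == pytest.approx(10.0, abs=0.5)

    def test_planar_set_raises(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-2, 2, 50), rng.uniform(-2, 2, 50),
                               np.zeros(50)])
        traj = _point_cloud_traj(pts, role=Role.DNA_BB, extra_dnt_axis=False)
        with pytest.raises(DegenerateAxisError):
            pore_axis(traj.frames[0], traj.topology)

    def test_too_few_particles_raises(self):
        traj = _point_cloud_traj(np.zeros((0, 3)), role=Role.DNA_BB,
                                 extra_dnt_axis=False)
        with pytest.raises(ValueError):
            pore_axis(traj.frames[0], traj.topology)


class TestRadialDensity:
    def test_uniform_annulus_density_is_analytic(self):
        rng = np.random.default_rng(1)
        n = 40_000
        r = np.sqrt(rng.uniform(1.0**2, 3.0**2, n))
        th = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-2, 2, n)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        traj = _point_cloud_traj(pts, box=(10, 10, 10))
        prof = radial_density(traj, [Role.WATER], shell_width=0.25,
                              cylinder_half_length=2.0, r_max=4.0)
        expected = n / (np.pi * (3.0**2 - 1.0**2) * 4.0)
        centres = prof.shell_centres
        covered = (centres > 1.3) & (centres < 2.7)
        dens = prof.density_per_role[Role.WATER][covered]
        assert dens == pytest.approx(expected, rel=0.05)

    def test_absent_role_gives_zero_profile(self, membrane_system):
        traj, _ = membrane_system
        prof = radial_density(traj, [Role.OTHER], r_max=3.0)
        assert np.all(prof.density_per_role[Role.OTHER] == 0)

    def test_density_volume_product_conserves_counts(self, membrane_system):
        traj, _ = membrane_system
        prof = radial_density(traj, [Role.LIPID_PO4, Role.ION_NA], r_max=6.0)
        for role in (Role.LIPID_PO4, Role.ION_NA):
            total = np.sum(prof.density_per_role[role] * prof.shell_volumes)
            assert total == pytest.approx(prof.mean_counts_per_role[role],
                                          rel=1e-6)

    def test_dna_density_peaks_at_wall_radius(self, membrane_system):
        traj, gt = membrane_system
        prof = radial_density(traj, [Role.DNA_BB], shell_width=0.2, r_max=6.0)
        peak_r = prof.shell_centres[np.argmax(prof.density_per_role[Role.DNA_BB])]
        # backbone sits between the lumen wall and the outer surface
        assert gt["lumen_radius"] - 0.3 <= peak_r <= gt["wall_radius"] + 0.3


class TestThickness:
    def test_flat_bilayer_recovers_h0(self):
        params = MembraneSystemParams(lipid_count=200, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      thinning_amplitude=0.0, seed=2)
        traj, gt = generate_membrane_system(params, n_frames=4)
        r, th = thickness_profile(traj, shell_width=0.3)
        ok = np.isfinite(th)
        assert th[ok] == pytest.approx(gt["bilayer_thickness_h0"], abs=0.1)

    def test_thinning_parameters_recovered_within_10_percent(self):
        params = MembraneSystemParams(lipid_count=400, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.03, seed=7)
        traj, gt = generate_membrane_system(params, n_frames=12)
        r, th = thickness_profile(traj, shell_width=0.1)
        h0, a, lam = fit_thinning(r, th, gt["wall_radius"])
        assert h0 == pytest.approx(gt["bilayer_thickness_h0"], rel=0.10)
        assert a == pytest.approx(gt["thinning_amplitude"], rel=0.10)
        assert lam == pytest.approx(gt["thinning_decay"], rel=0.10)

    def test_invariant_under_rigid_translation(self):
        params = MembraneSystemParams(lipid_count=150, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.0, seed=4)
        traj, _ = generate_membrane_system(params, n_frames=1)
        r1, th1 = thickness_profile(traj, shell_width=0.3)
        for f in traj.frames:
            f.positions += np.array([0.0, 0.0, 2.5])
        r2, th2 = thickness_profile(traj, shell_width=0.3)
        ok = np.isfinite(th1) & np.isfinite(th2)
        assert th2[ok] == pytest.approx(th1[ok], abs=1e-9)


class TestOrderParameter:
    def test_aligned_bonds_give_one(self):
        v = np.tile([0.0, 0.0, 0.47], (100, 1))
        assert order_parameter(v) == pytest.approx(1.0, abs=1e-12)

    def test_in_plane_bonds_give_minus_half(self):
        v = np.tile([0.47, 0.0, 0.0], (100, 1))
        assert order_parameter(v) == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_bonds_give_near_zero(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(10_000, 3))
        assert abs(order_parameter(v)) < 0.02

    @given(arrays(np.float64, (30, 3),
                  elements=st.floats(-1, 1, allow_nan=False)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_hold_for_any_bond_set(self, v):
        from hypothesis import assume
        assume(np.all(np.linalg.norm(v, axis=1) > 1e-9))
        s = order_parameter(v)
        assert -0.5 - 1e-9 <= s <= 1.0 + 1e-9

    def test_grid_recovers_generator_target(self, membrane_system):
        traj, gt = membrane_system
        grid = order_parameter_grid(traj, grid_cell=2.0)
        occupied = np.isfinite(grid.S)
        assert occupied.any()
        assert np.nanmean(grid.S) == pytest.approx(gt["order_param_target"],
                                                   abs=0.05)
        assert np.nanmin(grid.S) >= -0.5 and np.nanmax(grid.S) <= 1.0


class TestRDF:
    def test_poisson_gas_converges_to_one(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-5, 5, (3000, 3))
        traj = _point_cloud_traj(pts, box=(10, 10, 10), extra_dnt_axis=False)
        idx = select(traj.topology, roles=Role.WATER)
        res = rdf(traj, idx, idx, bin_width=0.1, r_max=3.0)
        far = res.r > 0.5
        assert np.mean(res.g[far]) == pytest.approx(1.0, abs=0.05)

    def test_fixed_pair_gives_single_bin_spike(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.7, 0.0, 0.0]])
        traj = _point_cloud_traj(pts, box=(10, 10, 10), extra_dnt_axis=False)
        res = rdf(traj, [0], [1], bin_width=0.05, r_max=2.0)
        assert res.r[np.argmax(res.g)] == pytest.approx(0.7, abs=0.05)
        assert (res.g > 0).sum() == 1

    def test_templated_contact_distance_sets_first_peak(self):
        rng = np.random.default_rng(3)
        n = 200
        centre = rng.uniform(-3, 3, (n, 3))
        shell_dir = rng.normal(size=(n, 3))
        shell_dir /= np.linalg.norm(shell_dir, axis=1, keepdims=True)
        pts = np.vstack([centre, centre + 0.9 * shell_dir])
        traj = _point_cloud_traj(pts, box=(12, 12, 12), extra_dnt_axis=False)
        res = rdf(traj, np.arange(n), np.arange(n, 2 * n), bin_width=0.05,
                  r_max=2.0)
        assert res.r[np.argmax(res.g)] == pytest.approx(0.9, abs=0.05)

    def test_empty_selection_rejected(self, membrane_system):
        traj, _ = membrane_system
        with pytest.raises(ValueError):
            rdf(traj, [], [1])


class TestIonSelectivity:
    @pytest.mark.parametrize("target", [1.0, 2.0, 14.0])
    def test_generated_ratio_recovered_within_ci(self, target):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_cation_anion_ratio=target,
                                      lumen_ion_count=300, bulk_ion_pairs=50,
                                      seed=int(target), jitter_sd=0.02)
        traj, gt = generate_membrane_system(params, n_frames=6)
        sel = ion_selectivity(traj, lumen_radius=gt["lumen_radius"],
                              lumen_half_length=gt["tube_length"] / 2)
        assert sel.ci_low <= gt["lumen_ratio"] <= sel.ci_high
        assert sel.ratio == pytest.approx(gt["lumen_ratio"], rel=0.25)

    def test_zero_anions_reports_infinite_ratio(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_cation_anion_ratio=float("inf"),
                                      lumen_ion_count=50, bulk_ion_pairs=0,
                                      seed=1)
        traj, gt = generate_membrane_system(params, n_frames=2)
        sel = ion_selectivity(traj, lumen_radius=gt["lumen_radius"],
                              lumen_half_length=gt["tube_length"] / 2)
        assert np.isinf(sel.ratio)
        assert sel.mean_na > 0
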