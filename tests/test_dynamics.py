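"""Residence times, tilt, displacement classification, SMD barriers,
unit conversion, r.m.s.d. and membrane deformation."""

import numpy as np
import pytest

from dntpore.dynamics import (classify_displacement, com_displacement,
                              force_to_piconewtons, membrane_deformation_track,
                              piconewtons_to_force, residence_times,
                              rmsd_partitioned, smd_barriers, tilt_series)
from dntpore.model import Frame, ParticleTopology, Trajectory, select
from dntpore.roles import DNT_ROLES, LIPID_ROLES, Role, RoleAssignment
from dntpore.synth import (MembraneSystemParams, SMDTraceParams,
                           generate_displacement_trace,
                           generate_membrane_system,
                           generate_residence_trajectory, generate_smd_trace)


def _contact_toy(contact_pattern, dt=50.0):
    """One DNA bead at origin plus one lipid bead toggling in/out of cutoff."""
    n_frames = len(contact_pattern)
    box = np.array([10.0, 10.0, 10.0])
    top = ParticleTopology.from_assignments(
        [RoleAssignment(Role.DNA_BB, bead_radius=0.26),
         RoleAssignment(Role.LIPID_PO4, bead_radius=0.26)],
        molecule_id=[0, 1], residue_index=[0, 1],
        names=["BB", "PO4"], resnames=["DNT", "POPC"],
    )
    frames = []
    for i, near in enumerate(contact_pattern):
        pos = np.array([[0.0, 0.0, 0.0],
                        [0.3 if near else 3.0, 0.0, 0.0]]) + box / 2
        frames.append(Frame(time=i * dt, box=box.copy(), positions=pos))
    return Trajectory(top, frames)


class TestResidenceTimes:
    def test_permanent_contact_is_single_window_spanning_event(self):
        traj = _contact_toy([1] * 10)
        rmap = residence_times(traj, [1], [0], cutoff=0.5)
        ((key, (mean_ps, n)),) = rmap.mean_residence().items()
        assert n == 1
        assert mean_ps == pytest.approx(10 * 50.0)

    def test_alternating_contacts_without_gap_merging(self):
        traj = _contact_toy([1, 0, 1, 0, 1, 0])
        rmap = residence_times(traj, [1], [0], cutoff=0.5, gap_tolerance=0)
        ((_, (mean_ps, n)),) = rmap.mean_residence().items()
        assert n == 3
        assert mean_ps == pytest.approx(50.0)  # one frame interval each

    def test_gap_tolerance_merges_across_single_frame_gaps(self):
        traj = _contact_toy([1, 0, 1, 0, 1, 0])
        rmap = residence_times(traj, [1], [0], cutoff=0.5, gap_tolerance=1)
        ((_, (mean_ps, n)),) = rmap.mean_residence().items()
        assert n == 1

    def test_total_contact_frames_conserved_across_events(self):
        pattern = [1, 1, 0, 1, 0, 0, 1, 1, 1, 0]
        traj = _contact_toy(pattern)
        rmap = residence_times(traj, [1], [0], cutoff=0.5, gap_tolerance=0)
        total = sum(ev.n_frames for ev in rmap.events)
        assert total == sum(pattern)

    def test_sn2_dwells_longer_than_sn1(self):
        """Fixture drawn with longer sn2 lifetimes reproduces the sn2 > sn1
        contact asymmetry at the DNA grooves."""
        traj, _ = generate_residence_trajectory(
            {("C2B", "minor"): 300.0, ("D2A", "minor"): 1200.0,
             ("C2B", "major"): 300.0, ("D2A", "major"): 1200.0},
            n_frames=600, seed=21)
        lip = select(traj.topology, roles=LIPID_ROLES)
        dna = select(traj.topology, roles=DNT_ROLES)
        rmap = residence_times(traj, lip, dna, cutoff=0.5,
                               groove_labels=["minor", "major"])
        means = rmap.mean_residence()
        for groove in ("minor", "major"):
            assert means[("D2A", groove)][0] > means[("C2B", groove)][0]


class TestTilt:
    def test_untilted_static_tube_is_below_one_degree(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.01, seed=2)
        traj, _ = generate_membrane_system(params, n_frames=4)
        angles, _, _ = tilt_series(traj)
        assert np.all(angles < 1.0)

    def test_constructed_45_degree_tilt(self):
        params = MembraneSystemParams(lipid_count=200, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      box=(30.0, 30.0, 30.0),
                                      tilt_angle=45.0, jitter_sd=0.005, seed=3)
        traj, _ = generate_membrane_system(params, n_frames=2)
        angles, _, _ = tilt_series(traj)
        assert np.mean(angles) == pytest.approx(45.0, abs=0.5)

    def test_wider_tilt_jitter_widens_the_distribution(self):
        def tilt_sd(jit, seed):
            params = MembraneSystemParams(lipid_count=120, water_count=0,
                                          lumen_ion_count=0, bulk_ion_pairs=0,
                                          tilt_angle=5.0, tilt_jitter_sd=jit,
                                          jitter_sd=0.005, seed=seed)
            traj, _ = generate_membrane_system(params, n_frames=12)
            angles, _, _ = tilt_series(traj)
            return np.std(angles)
        assert tilt_sd(3.0, 6) > tilt_sd(0.3, 6)


class TestDisplacement:
    def test_flat_zero_trace_relaxes_immediately(self):
        t = np.arange(0, 10_000, 100.0)
        trace = classify_displacement(t, np.zeros_like(t))
        assert trace.classification == "relaxed"
        assert trace.relaxation_time_ns == 0.0

    def test_monotone_drift_is_exited(self):
        t = np.arange(0, 100_000, 100.0)
        trace = classify_displacement(t, 1.0 + 0.0001 * t)
        assert trace.classification == "exited"

    @pytest.mark.parametrize("dz0,mode,expected", [
        (0.5, "relax", "relaxed"), (1.3, "relax", "relaxed"),
        (2.4, "relax", "relaxed"), (3.5, "exit", "exited"),
        (4.4, "exit", "exited"),
    ])
    def test_five_displacement_states_topology(self, dz0, mode, expected):
        """The five initial displacements: the three smaller ones relax back
        into the bilayer, the two that fully extract the hydrophobic band
        exit and diffuse away."""
        t, dz = generate_displacement_trace(dz0, mode, relax_time_ns=40.0,
                                            duration_ns=300.0, seed=13)
        trace = classify_displacement(t, dz, exit_threshold=4.5)
        assert trace.classification == expected
        if expected == "relaxed":
            assert 0.0 <= trace.relaxation_time_ns < 60.0

    def test_com_displacement_on_synthetic_system(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.01, seed=9)
        traj, _ = generate_membrane_system(params, n_frames=5)
        group = select(traj.topology, roles=DNT_ROLES)
        trace = com_displacement(traj, group)
        assert trace.classification == "relaxed"
        assert np.all(np.abs(trace.dz) < 0.3)


class TestSMDBarriers:
    def test_noiseless_bumps_extracted_exactly(self):
        trace, _ = generate_smd_trace(
            SMDTraceParams(entry_peak=1000.0, exit_peak=400.0, noise_sd=0.0))
        res = smd_barriers(trace)
        assert res.entry_barrier == pytest.approx(1000.0, rel=2e-3)
        assert res.exit_barrier == pytest.approx(400.0, rel=2e-3)
        assert res.entry_location_z == pytest.approx(-2.0, abs=0.2)
        assert res.exit_location_z == pytest.approx(2.0, abs=0.2)

    def test_band_free_tube_exits_without_resistance(self):
        """With no hydrophobic band (exit bump 0) the extracted exit barrier
        stays at the noise floor across seeds."""
        noise = 50.0
        for seed in range(20):
            trace, _ = generate_smd_trace(
                SMDTraceParams(entry_peak=1000.0, exit_peak=0.0,
                               noise_sd=noise, seed=seed))
            res = smd_barriers(trace)
            assert res.exit_barrier < 3 * noise

    def test_noisy_peak_extraction_is_unbiased(self):
        """Mean extracted peaks over 20 seeds within 2 SE of the truth."""
        entries, exits = [], []
        for seed in range(20):
            trace, _ = generate_smd_trace(
                SMDTraceParams(entry_peak=1000.0, exit_peak=400.0,
                               noise_sd=50.0, seed=seed))
            res = smd_barriers(trace)
            entries.append(res.entry_barrier)
            exits.append(res.exit_barrier)
        for sample, truth in ((entries, 1000.0), (exits, 400.0)):
            se = np.std(sample, ddof=1) / np.sqrt(len(sample))
            # smoothing bias is far below the noise scale; 2 SE + 1% slack
            assert abs(np.mean(sample) - truth) < 2 * se + 0.01 * truth

    def test_trace_not_crossing_bilayer_raises(self):
        trace, _ = generate_smd_trace(SMDTraceParams(noise_sd=0.0),
                                      duration_us=0.5)
        with pytest.raises(ValueError):
            smd_barriers(trace)


class TestForceConversion:
    def test_paper_scale_values(self):
        assert force_to_piconewtons(1000.0) == pytest.approx(1660.54, abs=0.01)
        assert force_to_piconewtons(500.0) == pytest.approx(830.27, abs=0.01)
        assert force_to_piconewtons(0.0) == 0.0

    def test_linear_and_invertible(self):
        assert force_to_piconewtons(2.0) == pytest.approx(
            2 * force_to_piconewtons(1.0), rel=1e-12)
        assert piconewtons_to_force(force_to_piconewtons(123.4)) == (
            pytest.approx(123.4, rel=1e-12))


class TestRMSD:
    def test_self_reference_is_zero(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.02, seed=5)
        traj, _ = generate_membrane_system(params, n_frames=1)
        tm, out = rmsd_partitioned(traj, traj.frames[0])
        assert tm[0] == pytest.approx(0.0, abs=1e-9)
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_removed_by_superposition(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.0, seed=5)
        traj, _ = generate_membrane_system(params, n_frames=2)
        ref = traj.frames[0]
        traj.frames[1].positions = traj.frames[1].positions + [1.0, -0.5, 0.7]
        tm, out = rmsd_partitioned(traj, ref)
        assert tm[1] == pytest.approx(0.0, abs=1e-9)
        assert out[1] == pytest.approx(0.0, abs=1e-9)

    def test_extra_jitter_outside_membrane_raises_outside_rmsd(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      jitter_sd=0.0, seed=5)
        traj, _ = generate_membrane_system(params, n_frames=2)
        ref = traj.frames[0]
        rng = np.random.default_rng(0)
        top = traj.topology
        dnt = top.role_mask(DNT_ROLES)
        z = ref.positions[:, 2] - np.mean(
            ref.positions[top.role_mask(Role.LIPID_PO4), 2])
        outside = dnt & (np.abs(z) > 2.0)
        traj.frames[1].positions[outside] += rng.normal(0, 0.3,
                                                        (outside.sum(), 3))
        tm, out = rmsd_partitioned(traj, ref)
        assert out[1] > tm[1]


class TestMembraneDeformation:
    def test_flat_bilayer_gives_straight_leaflet_lines(self):
        params = MembraneSystemParams(lipid_count=200, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      thinning_amplitude=0.0, jitter_sd=0.0,
                                      seed=6)
        traj, gt = generate_membrane_system(params, n_frames=1)
        _, x, curves = membrane_deformation_track(traj, lateral_bin=2.0)
        z_mid = traj.frames[0].box[2] / 2
        upper = curves[0, 0] - z_mid
        ok = np.isfinite(upper)
        # leaflet COM (headgroups + tails) sits inside the phosphate plane
        assert np.all(upper[ok] > 0)
        assert np.ptp(upper[ok]) < 0.3

    def test_imposed_dimple_depth_recovered(self):
        params = MembraneSystemParams(lipid_count=300, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      thinning_amplitude=0.0, jitter_sd=0.0,
                                      seed=6)
        traj, _ = generate_membrane_system(params, n_frames=1)
        frame = traj.frames[0]
        centre = frame.box / 2
        depth = 0.8
        lipid = traj.topology.role_mask(LIPID_ROLES)
        x = frame.positions[:, 0] - centre[0]
        y = frame.positions[:, 1] - centre[1]
        bump = depth * np.exp(-(x**2 + y**2) / (2 * 3.0**2))
        frame.positions[lipid, 2] -= bump[lipid]
        _, xc, curves = membrane_deformation_track(traj, lateral_bin=1.0)
        upper = curves[0, 0]
        ok = np.isfinite(upper)
        measured = np.nanmax(upper[ok]) - np.nanmin(upper[ok])
        assert measured == pytest.approx(depth, rel=0.25)

    def test_sampling_stride_matches_requested_interval(self):
        params = MembraneSystemParams(lipid_count=120, water_count=0,
                                      lumen_ion_count=0, bulk_ion_pairs=0,
                                      seed=1)
        traj, _ = generate_membrane_system(params, n_frames=10,
                                           frame_interval=1000.0)
        times, _, _ = membrane_deformation_track(traj, sample_every_ps=4000.0)
        assert np.all(np.diff(times) >= 4000.0 - 1e-9)
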