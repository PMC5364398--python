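import numpy as np
import pytest

from dntpore.builder import build_hexagonal_scaffold
from dntpore.model import Frame, ParticleTopology, Trajectory
from dntpore.roles import Role, RoleAssignment, builtin_dialect
from dntpore.synth import MembraneSystemParams, generate_membrane_system


@pytest.fixture(scope="session")
def cg_dialect():
    return builtin_dialect("cg-martini")


@pytest.fixture(scope="session")
def membrane_system():
    """Moderate synthetic DNT-in-bilayer trajectory shared across tests."""
    params = MembraneSystemParams(lipid_count=250, water_count=500,
                                  lumen_ion_count=150, bulk_ion_pairs=100,
                                  seed=11)
    return generate_membrane_system(params, n_frames=10, frame_interval=50.0)


@pytest.fixture(scope="session")
def dnt_model():
    return build_hexagonal_scaffold()


def make_tube_trajectory(helix_bead_radius=1.0, dz=0.1, half_length=5.0,
                         n_frames=1, box=(18.0, 18.0, 25.0)):
    """Ideal static tube: beads along each helix axis acting as solid cylinders."""
    model = build_hexagonal_scaffold()
    zs = np.arange(-half_length, half_length + dz / 2, dz)
    pts = np.array([[ax[0], ax[1], z] for ax in model.axis_points for z in zs])
    n = len(pts)
    top = ParticleTopology.from_assignments(
        [RoleAssignment(Role.DNA_BB, bead_radius=helix_bead_radius)] * n,
        molecule_id=np.zeros(n, int), residue_index=np.arange(n),
        names=["BB"] * n, resnames=["DNT"] * n,
    )
    box = np.asarray(box, float)
    centre = box / 2.0
    frames = [Frame(time=50.0 * i, box=box.copy(), positions=pts + centre)
              for i in range(n_frames)]
    return Trajectory(top, frames), model
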