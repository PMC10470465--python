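import pytest

from hyperrigid import (
    default_motion_spec,
    generate_trajectory,
    make_hypercube,
    perturb_vertices,
)


@pytest.fixture(scope="session")
def cube():
    return make_hypercube(3, 100.0)


@pytest.fixture(scope="session")
def hypercube():
    return make_hypercube(4, 100.0)


@pytest.fixture(scope="session")
def rigid_traj_4d(hypercube):
    """Jitter-free rigid hypercube trajectory at full presentation length."""
    spec = default_motion_spec(4, "rigid", jitter_amplitude=0.0)
    return generate_trajectory(hypercube, spec, seed=11)


@pytest.fixture(scope="session")
def sheared_traj_3d(cube):
    """Jitter-free non-rigid cube trajectory (x-axis shear + deformation)."""
    spec = default_motion_spec(3, "nonrigid", "x", jitter_amplitude=0.0)
    return generate_trajectory(cube, spec, seed=12)


def short_trajectory(dimension, kind, axis, irregularity, seed,
                     duration_s=1.0, frame_rate_hz=30.0):
    """Reduced-length stimulus used by the bulk oracle-agreement suites."""
    obj = make_hypercube(dimension, 100.0)
    if irregularity:
        obj = perturb_vertices(obj, irregularity, seed)
    spec = default_motion_spec(
        dimension,
        kind,
        axis if kind == "nonrigid" else None,
        jitter_amplitude=0.0,
        duration_s=duration_s,
        frame_rate_hz=frame_rate_hz,
    )
    return generate_trajectory(obj, spec, seed)
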