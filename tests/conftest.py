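import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strandroller.barrel_model import BarrelSurfaceModel, EllipseFit, SurfaceSlice
from strandroller.pipeline import detect
from strandroller.synthetic import BarrelSpec, generate_ideal_barrel, simulate_density

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def barrel8_truth():
    """Ideal circular 8-strand barrel at 45° tilt — the workhorse fixture."""
    return generate_ideal_barrel(BarrelSpec(n_strands=8, tilt_deg=45.0))


@pytest.fixture(scope="session")
def barrel8_map(barrel8_truth):
    return simulate_density(barrel8_truth.all_atoms, resolution=10.0, apix=1.0)


@pytest.fixture(scope="session")
def barrel8_detection(barrel8_map):
    return detect(barrel8_map)


def make_ideal_surface(
    radius: float,
    z_min: float = -10.0,
    z_max: float = 10.0,
    n_slices: int = 21,
    n_knots: int = 72,
) -> BarrelSurfaceModel:
    """Analytically perfect circular surface model for exact-geometry tests."""
    knot_az = np.linspace(-np.pi, np.pi, n_knots, endpoint=False)
    slices = []
    for z in np.linspace(z_min, z_max, n_slices):
        fit = EllipseFit(a=radius, b=radius, phi=0.0, center=np.zeros(2), residual=0.0)
        pts = np.column_stack(
            [radius * np.cos(knot_az), radius * np.sin(knot_az), np.full(n_knots, z)]
        )
        slices.append(
            SurfaceSlice(
                z=float(z),
                fit=fit,
                points=pts,
                azimuths=knot_az.copy(),
                radii=np.full(n_knots, radius),
            )
        )
    return BarrelSurfaceModel(
        slices=slices, z_min=z_min, z_max=z_max, n_angular_bins=n_knots
    )


@pytest.fixture
def ideal_surface():
    return make_ideal_surface(radius=8.643036635108217)  # closed 8-strand, 45°
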