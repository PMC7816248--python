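import numpy as np
import pytest

from napvc.phantom import PhantomSpec, simulate_phantom


@pytest.fixture(scope="session")
def phantom():
    """The default digital brain phantom, shared across the suite."""
    return simulate_phantom(PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for fast structural tests (crisp probabilities)."""
    from napvc.phantom import LesionSpec

    return PhantomSpec(
        grid_shape_highres=(96, 104, 80),
        brain_semiaxes=(40.0, 45.0, 32.0),
        lesions=(
            LesionSpec(center_mm=(4.0, 28.0, 14.0), radius_mm=7.0, tsc=70.0),
            LesionSpec(center_mm=(-18.0, -6.0, 2.0), radius_mm=9.0, tsc=30.0),
        ),
        gm_nuclei=(((-12.0, -9.0, 2.0), (7.0, 9.0, 7.0)),
                   ((12.0, -9.0, 2.0), (7.0, 9.0, 7.0))),
        cerebellum_center=(0.0, -27.0, -15.0),
        cerebellum_semiaxes=(24.0, 15.0, 11.0),
        ventricle_semiaxes=(5.0, 14.0, 6.0),
        ventricle_centers=((-8.0, -6.0, 2.0), (8.0, -6.0, 2.0)),
        tpm_softening_mm=0.0,
        tissue_confidence=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
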