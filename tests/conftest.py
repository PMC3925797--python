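import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biopsim.cohort import CohortSpec, Lesion, ProstateModel, build_cohort
from biopsim.geometry import Ellipsoid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_model(lesions, gland_semi=(26.0, 19.0, 21.0), urethra_y=-2.0,
               model_id="M1"):
    """Assemble a ProstateModel around hand-placed lesions."""
    gland = Ellipsoid(np.zeros(3), np.array(gland_semi))
    return ProstateModel(
        model_id=model_id,
        gland=gland,
        lesions=tuple(lesions),
        urethra_xy=(0.0, urethra_y),
        anus_reference=np.array([0.0, -(gland_semi[1] + 30.0), -(gland_semi[2] + 30.0)]),
    )


def spherical_lesion(center, radius, lesion_id="L1", gleason="7",
                     is_index=True, is_false_target=False):
    ell = Ellipsoid(np.asarray(center, float), np.full(3, float(radius)))
    return Lesion(
        id=lesion_id,
        volume_ml=ell.volume_ml,
        gleason=gleason,
        zone="posterior",
        ellipsoid=ell,
        is_index=is_index,
        is_false_target=is_false_target,
    )


@pytest.fixture
def sphere_target_model():
    """One ~1.0 ml spherical lesion centred on a template lattice point."""
    lesion = spherical_lesion([0.0, -2.0, 0.0], 6.2)
    return make_model([lesion])


@pytest.fixture(scope="session")
def paper_cohort():
    """The full-scale study cohort: 107 cancer glands plus benign targets."""
    return build_cohort(CohortSpec(n_prostates=107, seed=12345))


@pytest.fixture(scope="session")
def small_cohort():
    return build_cohort(CohortSpec(n_prostates=12, seed=7))
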