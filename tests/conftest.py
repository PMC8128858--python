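import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from bmupet import SuvVolume, BoneLabelVolume, score_focal
from bmupet.phantom import Lesion, PhantomSpec, generate_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: A phantom exercising both failure modes the detector must separate:
#: a genuine lesion inside a mid-thoracic vertebra and a hot node 3 mm
#: outside another vertebra whose blurred skirt leaks into the bone.
LESION_CENTER = (144.0, 144.0, 346.0)
NODE_CENTER = (168.0, 144.0, 424.0)


def lesion_phantom_spec() -> PhantomSpec:
    return PhantomSpec(
        lesions=(
            Lesion(LESION_CENTER, radius_mm=6.0, peak_suv=12.0, inside_bone=True),
            Lesion(NODE_CENTER, radius_mm=6.0, peak_suv=12.0, inside_bone=False),
        )
    )


@pytest.fixture(scope="session")
def lesion_phantom():
    suv, labels, manifest = generate_phantom(lesion_phantom_spec(), seed=7)
    return suv, labels, manifest


@pytest.fixture(scope="session")
def lesion_verdict(lesion_phantom):
    suv, labels, _ = lesion_phantom
    return score_focal(suv, labels)


def make_suv(values, spacing=(1.0, 1.0, 1.0)) -> SuvVolume:
    return SuvVolume(np.asarray(values, dtype=float), spacing)


def single_bone_volume(mask, spacing=(1.0, 1.0, 1.0), name="vertebra_L1") -> BoneLabelVolume:
    labels = np.where(np.asarray(mask, bool), 1, 0).astype(np.int16)
    return BoneLabelVolume(labels, {1: name}, spacing)
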