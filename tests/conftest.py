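import numpy as np
import pytest

from canalpose.synthetic import SubjectSpec, make_subject, random_rigid_pose


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free subject in canonical (identity) pose."""
    return make_subject(SubjectSpec.default(seed=101, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_subject():
    """Subject with 0.05 mm point noise, identity pose."""
    return make_subject(SubjectSpec.default(seed=202, noise_sd=0.05))


@pytest.fixture(scope="session")
def posed_subject_pair():
    """The same noisy subject in identity pose and under a random rigid pose."""
    rng = np.random.default_rng(303)
    pose = random_rigid_pose(rng)
    base = make_subject(SubjectSpec.default(seed=404, noise_sd=0.05))
    posed = make_subject(SubjectSpec.default(seed=404, noise_sd=0.05, pose=pose))
    return base, posed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
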