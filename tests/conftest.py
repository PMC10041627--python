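import numpy as np
import pytest

import elastimap as em


@pytest.fixture(scope="session")
def cubic_example() -> em.ElasticTensor:
    """Cubic tensor C11=12, C12=4, C44=3 GPa with closed-form moduli:
    E<100> = 10, E<111> = 7.8261, G on (001) = 3 GPa."""
    m = em.symmetry_class("cubic").build({(0, 0): 12.0, (0, 1): 4.0,
                                          (3, 3): 3.0})
    return em.ElasticTensor(m, source_label="cubic example")


@pytest.fixture(scope="session")
def iso10() -> em.ElasticTensor:
    """Isotropic E = 10 GPa, nu = 0.25 (C11=12, C12=4, C44=4, G = 4 GPa)."""
    return em.isotropic_stiffness(10.0, 0.25)


@pytest.fixture(scope="session")
def random_stable_set() -> list:
    """A reusable batch of seeded random stable triclinic tensors."""
    return [em.random_stable_stiffness("triclinic", seed=s)
            for s in range(20)]


def random_rotation(seed: int) -> np.ndarray:
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=np.random.default_rng(seed))


def random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
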