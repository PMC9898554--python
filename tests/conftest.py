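import numpy as np
import pytest

from equipair.model import AllegroConfig, AllegroModel
from equipair.synthetic import GeneratorSpec, ToyPotentialSpec, generate
from equipair.system import AtomicSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def e3_model():
    """Small full-parity model used for O(3) symmetry checks."""
    cfg = AllegroConfig(
        species=["H", "O"], r_cut=4.0, n_layers=2, ell_max=2, parity="e3",
        n_equivariant=2, two_body_dims=(8, 16), latent_dims=(16,),
        output_hidden=8, envelope_p=6, avg_num_neighbors=4.0, seed=11,
    )
    return AllegroModel(cfg)


@pytest.fixture(scope="session")
def se3_model():
    """Production-shaped small model (SE(3) mode)."""
    cfg = AllegroConfig.lithium_phosphate()
    cfg.avg_num_neighbors = 4.0
    cfg.seed = 7
    return AllegroModel(cfg)


@pytest.fixture(scope="session")
def water_like_cluster():
    rng = np.random.default_rng(5)
    pos = rng.uniform(0, 3.0, size=(5, 3))
    return AtomicSystem(["H", "O", "H", "H", "O"], pos)


@pytest.fixture(scope="session")
def lj_potential():
    return ToyPotentialSpec(
        "lennard_jones", {"eps": 0.5, "sigma": 1.8}, r_cut=4.0, envelope_p=6
    )


@pytest.fixture(scope="session")
def lj_frames(lj_potential):
    """Small labelled Lennard-Jones liquid dataset."""
    gen = GeneratorSpec(
        n_frames=24, n_atoms=6, composition=(("X", 1),), box=5.0,
        min_distance=1.5, seed=99,
    )
    return generate(gen, lj_potential)
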