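import numpy as np
import pytest

from confdiff.diffusion import DiffusionConfig, make_schedule
from confdiff.encoders import EncoderConfig
from confdiff.molgraph import MoleculeGraph
from confdiff.score_model import ScoreModel, ScoreModelConfig
from confdiff.toydata import ToySpec, make_toy


@pytest.fixture
def path4() -> MoleculeGraph:
    """A-B-C-D chain of single bonds (hop-edge workhorse)."""
    return make_toy(ToySpec(template="linear_chain", n_atoms=4))


@pytest.fixture
def ring6() -> MoleculeGraph:
    """Aromatic 6-ring (regular hexagon, bond length 1.4 A)."""
    return make_toy(ToySpec(template="ring", n_atoms=6, bond_length=1.4,
                            aromatic=True))


@pytest.fixture
def tet5() -> MoleculeGraph:
    """Five-carbon tetrahedral star, bond length 1.54 A."""
    return make_toy(ToySpec())


@pytest.fixture
def tiny_cfg() -> ScoreModelConfig:
    return ScoreModelConfig(
        encoder=EncoderConfig(hidden=16, n_filters=16, n_filters_reduced=8,
                              n_blocks=2, gin_depth=2),
        seed=11)


@pytest.fixture
def tiny_model(tiny_cfg) -> ScoreModel:
    model = ScoreModel(tiny_cfg)
    model.eval()
    return model


@pytest.fixture
def short_sched():
    return make_schedule(DiffusionConfig(T=50, beta_min=1e-5, beta_max=0.2))


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    tau = rng.normal(0.0, 5.0, size=3)
    return R, tau


# ---------------------------------------------------------------------------
# Shared overfit run: one tiny model trained on one rigid 5-atom molecule.
# Session-scoped because training takes minutes; reused by the trainer
# smoke test and the end-to-end sampling check.


@pytest.fixture(scope="session")
def overfit_run():
    from confdiff.trainer import TrainConfig, train, validate

    mol = make_toy(ToySpec())
    cfg = ScoreModelConfig(
        encoder=EncoderConfig(hidden=32, n_filters=32, n_filters_reduced=16,
                              n_blocks=2, gin_depth=2,
                              length_expansion="rbf"),
        seed=1)
    model = ScoreModel(cfg)
    sched = make_schedule(DiffusionConfig(T=100, beta_max=0.1))
    init_val = validate(model, [mol], sched, n_draws=4, seed=99)
    tcfg = TrainConfig(batch_size=64, val_interval=500, max_iterations=2000,
                       seed=7)
    state = train(tcfg, [mol], model, diffusion=sched)
    final_val = validate(model, [mol], sched, n_draws=4, seed=99)
    model.eval()
    return {"model": model, "sched": sched, "mol": mol, "state": state,
            "init_val": init_val, "final_val": final_val}
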