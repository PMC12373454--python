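import numpy as np
import pytest

from schemagaze.board import Board
from schemagaze.cohort import ScenarioConfig, generate_cohort
from schemagaze.policy import default_weights


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_board(rng, n_pieces=13):
    """A random (not necessarily win-free) board with balanced colors."""
    cells = np.zeros(36, dtype=np.int8)
    idx = rng.choice(36, size=n_pieces, replace=False)
    colors = np.tile([1, 2], 18)[:n_pieces]
    cells[idx] = colors
    return Board(cells.reshape(4, 9))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 4-subject Exp-2 cohort with moderate planted effects."""
    cfg = ScenarioConfig(design="exp2", n_subjects=4, n_blocks=3, preview_s=8.0)
    cfg.name = "tiny"
    cfg.fixation.lambda_enc = 0.25
    cfg.response.b_prob = 0.4
    cfg.response.b_pred = 0.3
    cfg.retrieval.g_pred = -0.2
    return generate_cohort(cfg, seed=11)
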