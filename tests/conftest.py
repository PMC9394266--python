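import numpy as np
import pytest

import mlppso as m
from mlppso import data_io, synthetic


@pytest.fixture
def xor_data():
    return synthetic.generate_xor()


@pytest.fixture
def small_synth():
    """200 moderately separable rows, a few missing cells in ca/thal."""
    return synthetic.generate(
        synthetic.SynthConfig(n_rows=200, effect_size=1.5, missing_rate=0.03, seed=7)
    )


@pytest.fixture
def cleveland_line():
    return "63,1,1,145,233,1,2,150,0,2.3,3,0,6,0"


@pytest.fixture
def cleveland_file(tmp_path, small_synth):
    path = tmp_path / "synthetic_cleveland.csv"
    data_io.write_cleveland_csv(small_synth, path)
    return path


@pytest.fixture
def trained_xor_model(xor_data):
    """A converged XOR model (seed chosen among the converging ones)."""
    from mlppso import pso, trainer

    cfg = pso.PSOConfig(swarm_size=100, max_iterations=100, seed=0)
    return trainer.train(xor_data, n_hidden=4, pso_config=cfg)
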