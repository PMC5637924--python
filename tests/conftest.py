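import numpy as np
import pytest

from lgphylo import simulate
from lgphylo.models import GTRModel


@pytest.fixture(scope="session")
def small_world():
    """A small simulated decaploid world shared by read-only tests."""
    seqs = simulate.simulate_progenitor_sequences(
        simulate.DEFAULT_SPECIES_TREE, 6000, GTRModel(), seed=11)
    mother, father, truth = simulate.assemble_polyploid(
        simulate.SCENARIOS["H2.C"], seqs, seed=12)
    pop = simulate.simulate_f1_cross(mother, father, truth, 45, 60.0, seed=13)
    return {"seqs": seqs, "mother": mother, "father": father,
            "truth": truth, "pop": pop}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
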