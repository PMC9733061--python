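import pytest

from cistrome.pipeline import run_pipeline
from cistrome.simulate import (
    SimConfig,
    default_cre_pfm,
    default_tre_pfm,
    simulate_all,
)


@pytest.fixture(scope="session")
def default_sim():
    """The reference synthetic run (default configuration, seed 1234)."""
    return simulate_all(SimConfig())


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    sim = default_sim
    return run_pipeline(
        sim.rep1, sim.rep2, sim.genes, sim.marks, sim.atac,
        sim.sequences, [default_tre_pfm(), default_cre_pfm()], sim.de_table,
    )


@pytest.fixture(scope="session")
def tre_pwm():
    return default_tre_pfm()


@pytest.fixture(scope="session")
def cre_pwm():
    return default_cre_pfm()
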