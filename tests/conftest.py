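import pytest

from ncsplice.core import Genome
from ncsplice.pipeline import run_pipeline
from ncsplice.pwm import ClassifierConfig
from ncsplice.simulate import SimulationConfig, simulate_evidence, simulate_reference


@pytest.fixture(scope="session")
def toy_genome():
    return Genome({"chr1": "AAAGTATCCAGAAA"})


@pytest.fixture(scope="session")
def sim_world():
    """Default-condition synthetic world: genome, truth, evidence."""
    cfg = SimulationConfig(seed=0)
    genome, truths = simulate_reference(cfg)
    records, variants, pileup = simulate_evidence(genome, truths, cfg)
    return cfg, genome, truths, records, variants, pileup


@pytest.fixture(scope="session")
def sim_result(sim_world):
    """Pipeline result over the default synthetic world."""
    cfg, genome, truths, records, variants, pileup = sim_world
    result = run_pipeline(
        genome,
        records,
        variants=variants,
        pileup=pileup,
        classifier_config=ClassifierConfig(seed=cfg.seed),
    )
    return cfg, genome, truths, result
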