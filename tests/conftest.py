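import numpy as np
import pytest

from yprime.core import PipelineConfig
from yprime.simulate import SimulationSpec, build_templates, simulate_genome


@pytest.fixture(scope="session")
def templates():
    return build_templates(0)


@pytest.fixture(scope="session")
def template_map(templates):
    return {t.class_name: t for t in templates}


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim(templates):
    """One small simulated strain shared by read-only tests."""
    spec = SimulationSpec(
        n_strains=1,
        contigs_per_strain=3,
        elements_per_end=(0.2, 0.4, 0.3, 0.1),
        seed=11,
    )
    genomes, truth = simulate_genome(spec, templates)
    return spec, genomes, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
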