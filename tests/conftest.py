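import numpy as np
import pytest
from hypothesis import settings

from cutsurvey.genomic_io import Annotation, Genome
from cutsurvey.pipeline import conservation_analysis, run_world
from cutsurvey.simulate import SimulationConfig, simulate_world

settings.register_profile("default", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def world():
    """The default synthetic world (seed 1), shared across tests."""
    return simulate_world(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def world_results(world):
    """Full calling pipeline on every strain of the shared world."""
    return run_world(world)


@pytest.fixture(scope="session")
def world_conservation(world, world_results):
    """(regions, per-call classes, alignment map) for the shared world."""
    return conservation_analysis(world, world_results)


@pytest.fixture
def toy_genome():
    return Genome({"chrI": 10_000, "chrII": 5_000})


def make_ann(chrom="chrI", start=0, end=100, strand="+", name="x", fclass=""):
    return Annotation(chrom, start, end, strand, name, fclass)
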