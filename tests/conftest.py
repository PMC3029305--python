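import numpy as np
import pytest

from snpbsa.genetic_models import GeneticMap, QTLLocus, QTLModel


@pytest.fixture
def small_map() -> GeneticMap:
    """Five short chromosomes with 2 cM marker spacing — fast to simulate."""
    lengths = {"1": 50.0, "2": 60.0, "3": 50.0, "4": 50.0, "5": 50.0}
    return GeneticMap.uniform(lengths, spacing_cM=2.0)


@pytest.fixture
def two_marker_map() -> GeneticMap:
    """Single chromosome with two markers 10 cM apart."""
    return GeneticMap(lengths_cM={"1": 10.0}, markers={"1": np.array([0.0, 10.0])})


@pytest.fixture
def additive_model() -> QTLModel:
    return QTLModel(loci=(QTLLocus("2", 36.0, a=1.0),), env_sd=1.0, reps_per_line=3)
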