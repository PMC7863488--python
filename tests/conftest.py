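import numpy as np
import pytest

from kgadr.kg import KnowledgeGraph, Triple


@pytest.fixture
def tiny_kg() -> KnowledgeGraph:
    """Three triples touching all three relations."""
    return KnowledgeGraph(
        [
            Triple("D1", "has_side_effect", "S1"),
            Triple("D1", "has_target", "T1"),
            Triple("D2", "has_indication", "I1"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
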