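import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phixlink.config import PipelineConfig
from phixlink.datamodel import Chain, ProteinRecord, StructureModel


@pytest.fixture
def config():
    return PipelineConfig(core_subunits=("CORE1", "CORE2"))


@pytest.fixture
def line_structure():
    """Two straight chains 30 Å apart; distances are trivially computable.

    Chain A: protein PA, residues 1..10 at (3.8*i, 0, 0).
    Chain B: protein PB, residues 1..10 at (3.8*i, 30, 0).
    """
    n = 10
    xs = 3.8 * np.arange(n)
    seq = "KSTYAKSTYA"
    a = Chain("A", np.arange(1, n + 1), seq,
              np.column_stack([xs, np.zeros(n), np.zeros(n)]))
    b = Chain("B", np.arange(1, n + 1), seq,
              np.column_stack([xs, np.full(n, 30.0), np.zeros(n)]))
    model = StructureModel("line", [a, b], {"A": "PA", "B": "PB"})
    proteins = [ProteinRecord("PA", seq), ProteinRecord("PB", seq)]
    return model, proteins
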