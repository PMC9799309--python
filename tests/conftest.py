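import numpy as np
import pytest

from metox.structure import select_methionines
from metox.synthetic import ProbeSpec, build_probe
from metox.tables import load_reference_tables


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def solvated_probe():
    """A methionine probe with 6 shell waters and 2 shell hydroxyls."""
    spec = ProbeSpec(
        n_waters_in=6, n_waters_out=4, n_ser_in=1, n_thr_in=1, seed=11
    )
    model, truth = build_probe(spec)
    return model, truth


@pytest.fixture
def probe_site(solvated_probe):
    model, _ = solvated_probe
    return select_methionines(model)[0]
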