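import dataclasses

import pytest
from hypothesis import settings

import g4topo as g
from g4topo.foldability import label_foldable
from g4topo.simulate import GenerativeParams
from g4topo.topology import CANONICAL_LOOP_ORDER

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def all_topologies():
    return g.enumerate_topologies()


@pytest.fixture(scope="session")
def rh_grid_3t():
    """Full three-tetrad right-handed conformational grid (13,312 cells)."""
    return g.enumerate_conformations(3, (1, 4), "RH")


@pytest.fixture(scope="session")
def labeled_records(rh_grid_3t):
    """Synthetic foldability records over the full 3T RH grid, labeled by
    the default RMSD thresholds."""
    records = g.generate_records(rh_grid_3t, GenerativeParams(seed=20250911))
    return label_foldable(records)


@pytest.fixture(scope="session")
def loop_tokens():
    return [str(lt) for lt in CANONICAL_LOOP_ORDER]
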