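import numpy as np
import pytest

from chromage import SimulationConfig, default_human_ladder
from chromage.dating import Branch, BranchLadder


@pytest.fixture(scope="session")
def ladder():
    return default_human_ladder()


def make_toy_ladder(n_outgroups: int) -> BranchLadder:
    """Ladder with single-species outgroups sp0..sp{n-1} (sp0 most distant)."""
    branches = []
    for i in range(n_outgroups):
        start = -100.0 * (n_outgroups - i + 1)
        end = -100.0 * (n_outgroups - i)
        branches.append(
            Branch(index=i, outgroups=frozenset({f"sp{i}"}),
                   age_start=start, age_end=end,
                   midpoint=-1000.0 if i == 0 else (start + end) / 2.0)
        )
    branches.append(
        Branch(index=n_outgroups, outgroups=frozenset(),
               age_start=-100.0, age_end=0.0, midpoint=-50.0)
    )
    return BranchLadder(focal="focal", branches=branches)


@pytest.fixture(scope="session")
def toy_ladder():
    return make_toy_ladder(5)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions: same rates, ~2,600 genes."""
    return SimulationConfig(
        seed=11,
        gene_counts=(900, 60, 60, 70, 90, 500, 120, 120, 180, 120, 100, 120, 160),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
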