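import warnings

import pytest

from preypred.hexworld import Environment, HexCell

warnings.filterwarnings("ignore", category=UserWarning, module="arviz")
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_env():
    """Wall-free 21x10 grid with a tree cluster, red patch and some coins."""
    return Environment(
        trees=frozenset({HexCell(15, 3), HexCell(15, 4), HexCell(16, 3)}),
        red_ground=frozenset({HexCell(4, 6), HexCell(5, 6), HexCell(5, 7)}),
        coins=frozenset({HexCell(8, 2), HexCell(10, 8)}),
        predator_start=HexCell(0, 2), prey_start=HexCell(10, 5))


@pytest.fixture(scope="session")
def corridor_env():
    """1 x 7 corridor with a coin two steps west of the prey."""
    return Environment(
        width=7, height=1,
        coins=frozenset({HexCell(1, 0)}),
        predator_start=HexCell(6, 0), prey_start=HexCell(3, 0),
        moves_per_turn_prey=1, moves_per_turn_predator=1, n_turns=3)
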