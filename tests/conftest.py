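from pathlib import Path

import pytest

from stemnode import fig1_tree, fig3_tree

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fig1_node():
    return fig1_tree("node")


@pytest.fixture(scope="session")
def fig1_stem():
    return fig1_tree("stem")


@pytest.fixture(scope="session")
def fig3_node():
    return fig3_tree("node")


@pytest.fixture(scope="session")
def fig3_stem():
    return fig3_tree("stem")


@pytest.fixture(scope="session")
def data_dir():
    return DATA
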