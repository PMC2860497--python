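import numpy as np
import pytest

from mdgsa import GeneRanking, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        sets={
            "S1": ("g01", "g02", "g03"),
            "S2": ("g02", "g04"),
        },
        descriptions={"S1": "first set", "S2": "second set"},
    )


@pytest.fixture
def gmt_file(tmp_path):
    """Factory writing GMT content and returning the path."""

    def _write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def ranking_2d(rng):
    n = 400
    values = rng.standard_normal((n, 2))
    genes = tuple(f"g{i:04d}" for i in range(n))
    return GeneRanking(universe=genes, values=values, dimension_names=("X", "Y"))
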