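import numpy as np
import pytest

from antithesis_cpi import ScoreMatrix, ZMatrix, DrugRoster, twodiz


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_matrix(rng):
    """Complete 8x5 raw score matrix."""
    vals = rng.normal(size=(8, 5))
    return ScoreMatrix(
        drug_ids=[f"D{j}" for j in range(5)],
        pocket_ids=[f"P{i}" for i in range(8)],
        values=vals,
        missing=np.zeros((8, 5), dtype=bool),
    )


@pytest.fixture
def toy_zmatrix():
    """One pocket with Z' = (0, 1, 2, 3) plus a second filler pocket."""
    vals = np.array([[0.0, 1.0, 2.0, 3.0], [0.5, -0.5, 1.5, -1.5]])
    return ZMatrix(
        drug_ids=["A", "B", "C", "D"],
        pocket_ids=["P0", "P1"],
        values=vals,
        missing=np.zeros_like(vals, dtype=bool),
    )


@pytest.fixture
def roster():
    roles = {f"CASE{i}": "case" for i in range(3)}
    roles.update({f"CTRL{i}": "control" for i in range(2)})
    roles["BG0"] = "background"
    return DrugRoster(roles=roles)
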