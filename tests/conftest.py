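import numpy as np
import pytest

from lovspec import synth


@pytest.fixture(scope="session")
def wl_grid():
    return np.arange(300.0, 701.0, 1.0)


@pytest.fixture(scope="session")
def flavin_basis(wl_grid):
    return synth.make_flavin_basis(wl_grid)


@pytest.fixture(scope="session")
def ta_scene():
    """A canonical two-component TA ground truth: decaying triplet-minus-ground
    DADS plus a non-decaying radical-pair DADS."""
    grid = np.linspace(340.0, 680.0, 100)
    basis = synth.make_flavin_basis(grid)
    dads1 = basis["Triplet"].with_values(
        basis["Triplet"].values - basis["FMNox"].values, label="DADS1"
    )
    dads2 = basis["FMNHrad"].with_values(
        basis["FMNHrad"].values - basis["FMNox"].values, label="DADS2"
    )
    return {
        "grid": grid,
        "basis": basis,
        "dads": [dads1, dads2],
        "lifetimes": [28.0, np.inf],
        "t0": 2.0,
        "irf_sigma": 0.4,
        "times": np.linspace(0.0, 200.0, 512),
    }


MINI_PDB = """\
HETATM    1  N5  FMN A 501      10.000  10.000  10.000  1.00  0.00           N
HETATM    2  C4A FMN A 501      11.400  10.000  10.000  1.00  0.00           C
HETATM    3  C10 FMN A 501      12.100  11.200  10.000  1.00  0.00           C
HETATM    4  P   FMN A 501      20.000  20.000  20.000  1.00  0.00           P
ATOM      5  CZ  TYR A  59       5.000  10.000  10.000  1.00  0.00           C
ATOM      6  OH  TYR A  59       3.600  10.000  10.000  1.00  0.00           O
ATOM      7  CB  TYR A  59       7.500  10.000  10.000  1.00  0.00           C
ATOM      8  HH  TYR A  59       3.000  10.000  10.000  1.00  0.00           H
ATOM      9  CG ATRP A  67       0.000   0.000   0.000  1.00  0.00           C
ATOM     10  CG BTRP A  67       1.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    """Synthetic miniature PDB fixture: FMN ring fragment, Tyr ring fragment
    with a hydrogen, and an altloc A/B pair."""
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path
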