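import numpy as np
import pytest

from gridpocket import (
    FixtureSpec,
    compute_descriptor,
    default_forcefield,
    make_hollow_shell,
    normalize,
)


@pytest.fixture(scope="session")
def forcefield():
    return default_forcefield()


@pytest.fixture(scope="session")
def shell_fixture():
    """One sealed hollow-shell fixture shared across tests."""
    spec = FixtureSpec(seed=42)
    protein, site = make_hollow_shell(spec)
    return spec, protein, site


@pytest.fixture(scope="session")
def shell_descriptor(shell_fixture):
    _, protein, site = shell_fixture
    raw = compute_descriptor(protein)
    return raw, normalize(raw), site


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


PDBQT_3ATOMS = [
    "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00    -0.300 N ",
    "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00     0.100 C ",
    "ATOM      3  O   ALA A   1       0.000   2.000   0.000  1.00  0.00     0.200 OA",
]
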