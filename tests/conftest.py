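import numpy as np
import pytest

from lipotrace.isotope_chem import IsotopeTable, monoisotopic_table, parse_formula
from lipotrace.mid_correction import CorrectionSpec, build_correction_matrix


@pytest.fixture(scope="session")
def palmitate_spec() -> CorrectionSpec:
    """Default TBDMS-palmitate correction spec (16 tracer carbons)."""
    return CorrectionSpec()


@pytest.fixture(scope="session")
def palmitate_matrix(palmitate_spec) -> np.ndarray:
    return build_correction_matrix(palmitate_spec)


@pytest.fixture(scope="session")
def carbon_only_table() -> IsotopeTable:
    """Isotope table where only carbon has a heavy isotope (13C at 0.0107)."""
    return IsotopeTable(
        shifts={"C": [0, 1], "H": [0], "O": [0], "Si": [0], "N": [0], "S": [0]},
        abundances={"C": [0.9893, 0.0107], "H": [1.0], "O": [1.0],
                    "Si": [1.0], "N": [1.0], "S": [1.0]},
    )


@pytest.fixture(scope="session")
def mono_table() -> IsotopeTable:
    return monoisotopic_table()


def random_mid(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random normalized non-negative MID of length n."""
    x = rng.random(n)
    return x / x.sum()
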