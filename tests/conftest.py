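import numpy as np
import pytest

from urinemet.synthetic_data import CohortSpec, build_template_library, simulate_cohort

MARKER_DIRECTIONS = {
    "alanine": "up",
    "citrate": "up",
    "creatine": "up",
    "creatinine": "down",
    "glycerol": "down",
    "hippurate": "up",
    "phenylalanine": "up",
    "taurine": "up",
    "3-hydroxybutyrate": "down",
}

# every printed (shift, multiplicity) pair of the nine marker metabolites
MARKER_PEAKS = {
    "alanine": [(1.49, "doublet")],
    "citrate": [(2.54, "doublet"), (2.68, "doublet")],
    "creatine": [(3.04, "singlet")],
    "creatinine": [(3.05, "singlet"), (4.07, "singlet")],
    "glycerol": [(3.57, "multiplet"), (3.66, "multiplet"), (3.78, "multiplet")],
    "hippurate": [(3.98, "doublet"), (7.55, "triplet"), (7.64, "triplet"), (7.83, "multiplet")],
    "phenylalanine": [(7.32, "multiplet"), (7.38, "multiplet"), (7.42, "multiplet")],
    "taurine": [(3.27, "triplet"), (3.43, "triplet")],
    "3-hydroxybutyrate": [(1.21, "doublet")],
}


@pytest.fixture(scope="session")
def library():
    return build_template_library()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (20+20 subjects, coarse grid) for fast unit tests."""
    spec = CohortSpec(n_control=20, n_case=20, n_points=8192, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
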