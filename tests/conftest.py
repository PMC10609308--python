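import random

import pytest
from hypothesis import HealthCheck, settings

from straintag import SimScenario, make_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Table 2 of the published assay: primer code, sequence (5'->3'), printed
# length, Tm (deg C), GC (%) and multiplex product length (bp).
TABLE2 = [
    ("6.2F", "CCCGATAGAGGTTCTTCAAGCC", 22, 60.48, 54.55, 183),
    ("6.2R", "ACTCCAAGGATCCAAACAAGCC", 22, 60.82, 50.00, 183),
    ("10.16F", "CGATTGCAGCAACGATAGATCC", 22, 59.84, 50.00, 405),
    ("10.16R", "TAGACCCATTTTGCCAAGGTC", 21, 58.20, 47.62, 405),
    ("12.1F", "AGGAGCAATGTGATTCTACCAC", 22, 58.12, 45.45, 223),
    ("12.1R", "AGGCAATGCTATCGTCCATGA", 21, 59.58, 47.62, 223),
    ("2.2F", "CATATCGTCAACAATCCCACGG", 22, 59.46, 50.00, 135),
    ("2.2R", "TAGCACTGTGGCTGAGTATTGG", 22, 60.09, 50.00, 135),
    ("6.5F", "TACTTTCTGATCTGGTCGGGTC", 22, 59.24, 50.00, 380),
    ("6.5R", "GCTTTACCGGACATCCTCAATG", 22, 59.39, 50.00, 380),
    ("9.8F", "TGTTTTGGGTATAGCTGTGGC", 21, 58.56, 47.62, 245),
    ("9.8R", "CGAACTCGGGCTAGAAATCATC", 22, 58.95, 50.00, 245),
]

# the two published tetraplex fingerprints (strain-specific bands only)
L125_BANDS = [405, 223, 183]
L33_BANDS = [380, 245, 135]


@pytest.fixture(scope="session")
def table2():
    return TABLE2


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-scale synthetic study shared by the integration-style tests."""
    scenario = SimScenario(
        seed=11,
        backbone_len=30_000,
        n_siblings=2,
        nontarget_len=30_000,
        islands=((1500, 2),),
    )
    return make_scenario(scenario)
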