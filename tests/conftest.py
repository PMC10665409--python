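import numpy as np
import pandas as pd
import pytest

import meiokit as mk
from meiokit.simulate import FamilyDesign


@pytest.fixture(scope="session")
def desk():
    """Desk-scale study conditions (genome, panel, landscape, trait, design)."""
    return mk.desk_preset()


@pytest.fixture(scope="session")
def clean_sim(desk):
    """Error-free desk simulation reused by phasing/phenotype/map tests."""
    genome, panel, landscape, trait, _ = desk
    design = FamilyDesign(n_sires=6, n_dams=6, offspring_per_family=20)
    return mk.simulate_population(
        genome, panel, landscape, trait, design,
        error_rate=0.0, missing_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def clean_vectors(clean_sim):
    return mk.phase_population(
        clean_sim.pedigree, clean_sim.genotypes,
        min_offspring=4, segregation_alpha=None, run_mendel=False,
    )


@pytest.fixture
def toy_panel():
    return mk.MarkerPanel(
        tuple(f"m{i}" for i in range(6)),
        ("c1",) * 3 + ("c2",) * 3,
        (10, 20, 30, 10, 20, 30),
        ("A",) * 6,
        ("B",) * 6,
    )


@pytest.fixture
def toy_pedigree():
    return mk.Pedigree(
        pd.DataFrame(
            {
                "id": ["S1", "D1", "K1", "K2"],
                "sire": [None, None, "S1", "S1"],
                "dam": [None, None, "D1", "D1"],
                "sex": ["male", "female", "unknown", "unknown"],
            }
        )
    )
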