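import numpy as np
import pandas as pd
import pytest

import breedgain as bg


@pytest.fixture(scope="session")
def tiny_pedigree() -> pd.DataFrame:
    """Hand-built pedigree with known relationships.

    A, B founders; C = A x B (full sib of D); D = A x B; E = C x A
    (backcross); S = selfed founder F.
    """
    return pd.DataFrame({
        "genotype": ["A", "B", "C", "D", "E", "F", "S"],
        "parent_f": [None, None, "A", "A", "C", None, "F"],
        "parent_m": [None, None, "B", "B", "A", None, "F"],
    })


@pytest.fixture(scope="session")
def small_config() -> bg.SimConfig:
    return bg.SimConfig(
        n_founders=20, crosses_per_year=20, n_years_crossing=6,
        n_trial_years=6, entries_per_trial=60, seed=11,
    )


@pytest.fixture(scope="session")
def small_program(small_config):
    ped, truth, pheno = bg.simulate_program(small_config)
    return ped, truth, pheno


@pytest.fixture(scope="session")
def small_stage1(small_program):
    _, _, pheno = small_program
    cleaned, _ = bg.run_qc(pheno)
    return bg.stage1_by_year(cleaned)


@pytest.fixture(scope="session")
def small_amatrix(small_program):
    ped, _, _ = small_program
    return bg.build_a_matrix(ped)


@pytest.fixture(scope="session")
def small_stage2(small_stage1, small_amatrix):
    return bg.stage2_blup(small_stage1, small_amatrix)


def balanced_rcbd(rng, n_geno=20, n_reps=3, mu=3000.0, sg=200.0, se=100.0,
                  year=2000, season="DS"):
    """Single-trial balanced RCBD phenotype table with IID genotype values."""
    gv = rng.normal(0, sg, n_geno)
    rows = []
    for rep in range(n_reps):
        re_ = rng.normal(0, 50)
        for i in range(n_geno):
            rows.append({
                "genotype": f"g{i:02d}", "year": year, "season": season,
                "location": "L", "design": "rcbd", "rep": str(rep + 1),
                "block": str(rep + 1), "row": None, "col": None,
                "yield_kg_ha": mu + gv[i] + re_ + rng.normal(0, se),
                "dtf": 90,
            })
    return pd.DataFrame(rows), gv
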