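import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gxescan.synthetic_data import SimScenario, simulate_cohort, write_fixture_bundle
from gxescan.types import CohortTable, GenotypeMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


SMALL_SCENARIO = SimScenario(
    n_cases=400, n_controls=400, n_genes=3, snps_per_gene=8,
    weight_sparsity=0.6, seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across read-only tests."""
    return simulate_cohort(SMALL_SCENARIO)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(SMALL_SCENARIO, out)
    return paths


def make_genotypes(dosages, effect=None, other=None, r2=None, ids=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": ids or [f"v{j}" for j in range(m)],
        "effect_allele": effect or ["A"] * m,
        "other_allele": other or ["G"] * m,
        "imputation_r2": r2 if r2 is not None else [0.9] * m,
    })
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


def make_cohort(outcome, bmi=None, diabetes=None, sex=None, age=None,
                study=None, pcs=1):
    """Hand-build a CohortTable (bmi given in per-5 units)."""
    n = len(outcome)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "outcome": outcome,
        "bmi": bmi if bmi is not None else rng.uniform(4.0, 7.0, n),
        "diabetes": diabetes if diabetes is not None else rng.integers(0, 2, n),
        "sex": sex if sex is not None else np.where(np.arange(n) % 2, "male", "female"),
        "age": age if age is not None else rng.normal(60, 8, n),
        "study": study if study is not None else ["study00"] * n,
    })
    for k in range(pcs):
        df[f"pc{k + 1}"] = rng.normal(size=n)
    return CohortTable(data=df)
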