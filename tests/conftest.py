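import importlib.resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thrombomark import ClinicalCohort, ExpressionMatrix
from thrombomark.containers import TCGA_SUBTYPES
from thrombomark.synthetic import CohortSpec, ExpressionSpec, simulate_cohort, simulate_expression

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the shipped published-value tables."""
    ref = importlib.resources.files("thrombomark.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


@pytest.fixture(scope="session")
def reported_balance() -> pd.DataFrame:
    return load_fixture("reported_balance_table.tsv")


@pytest.fixture(scope="session")
def reported_de_diffuse() -> pd.DataFrame:
    return load_fixture("reported_de_diffuse.tsv")


@pytest.fixture(scope="session")
def reported_de_intestinal() -> pd.DataFrame:
    return load_fixture("reported_de_intestinal.tsv")


@pytest.fixture(scope="session")
def reported_subtype_de() -> pd.DataFrame:
    return load_fixture("reported_subtype_de.tsv")


def make_planted_subtype_data(seed: int, n_samples: int = 100, per_subtype: int = 6):
    """Cohort + matrix where a few samples per subtype express their marker
    block at 3 baseline-SD and the rest carry no signature (ambiguous).

    Returns (cohort, matrix, signatures-dict, truth: sample -> subtype,
    ambiguous sample ids).
    """
    cohort = simulate_cohort(CohortSpec(n_patients=n_samples, seed=seed))
    rng = np.random.default_rng(seed + 1_000)
    ids = list(cohort.table["patient_id"])
    order = rng.permutation(ids)
    truth: dict[str, str] = {}
    t = cohort.table.copy()
    for i, s in enumerate(TCGA_SUBTYPES):
        chosen = list(order[i * per_subtype : (i + 1) * per_subtype])
        t.loc[t["patient_id"].isin(chosen), "true_subtype"] = s
        truth.update({x: s for x in chosen})
    ambiguous = [x for x in ids if x not in truth]
    cohort = ClinicalCohort(t, cohort.covariates)
    signatures = {
        s: (
            [f"{s}_UP_{i:02d}" for i in range(40)],
            [f"{s}_DN_{i:02d}" for i in range(40)],
        )
        for s in TCGA_SUBTYPES
    }
    baseline_sd = 0.5
    spec = ExpressionSpec(
        n_genes=1000,
        baseline_sd=baseline_sd,
        subtype_signatures=signatures,
        signature_shift=3 * baseline_sd,
        ambiguous_samples=ambiguous,
        seed=seed + 2_000,
    )
    matrix = simulate_expression(cohort, spec)
    return cohort, matrix, signatures, truth, ambiguous


def tiny_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
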