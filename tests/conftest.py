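import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pathburden.io import ClinicalTable, GeneSetCollection, MutationTable


@pytest.fixture
def tiny_mutations() -> MutationTable:
    """Three samples; P1 carries FASN twice + ACACA, P2 one silent FASN."""
    rec = pd.DataFrame(
        {
            "sample_id": ["P1", "P1", "P1", "P2", "P3"],
            "gene": ["FASN", "FASN", "ACACA", "FASN", "TP53"],
            "variant_class": [
                "Missense_Mutation",
                "Nonsense_Mutation",
                "Missense_Mutation",
                "Silent",
                "Missense_Mutation",
            ],
            "protein_change": [pd.NA] * 5,
        }
    )
    return MutationTable(rec)


@pytest.fixture
def fa_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {"FA": {"FASN", "ACACA", "PTGIS"}, "OTHER": {"TP53", "RB1"}}
    )


@pytest.fixture
def small_clinical() -> ClinicalTable:
    rng = np.random.default_rng(7)
    n = 12
    data = pd.DataFrame(
        {
            "time": rng.exponential(10, n).round(2) + 0.5,
            "event": rng.integers(0, 2, n),
            "age": rng.normal(60, 8, n).round(1),
        },
        index=pd.Index([f"P{k}" for k in range(n)], name="sample_id"),
    )
    data.iloc[0, data.columns.get_loc("event")] = 1
    return ClinicalTable(data, covariate_kinds={"age": "continuous"})
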