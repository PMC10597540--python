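import numpy as np
import pandas as pd
import pytest

from episub import CohortMetadata, ExpressionMatrix, SimParams, simulate_cohort
from episub.containers import MODALITIES


@pytest.fixture(scope="session")
def default_cohort():
    """One study-shaped synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimParams(seed=11))


def make_metadata(
    n: int,
    outcome=None,
    batch=None,
    rng_seed: int = 0,
    pathology=None,
) -> CohortMetadata:
    rng = np.random.default_rng(rng_seed)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    if outcome is None:
        outcome = rng.integers(0, 2, n)
    df = pd.DataFrame(
        {
            "outcome": np.asarray(outcome, dtype=int),
            "sex": rng.integers(0, 2, n),
            "pathology": pathology if pathology is not None
            else rng.choice(
                ["hippocampal sclerosis", "no lesion", "other",
                 "malformations of cortical development"], n),
            "surgical_side": rng.integers(0, 2, n),
            "epilepsy_duration": rng.uniform(1, 40, n).round(1),
            "batch": batch if batch is not None else ["b1"] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    for m in MODALITIES:
        df[f"has_{m}"] = True
    return CohortMetadata(df)


def make_matrix(values, modality="blood_mirna", unit="scaled", feature_ids=None,
                sample_ids=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    fids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
    sids = sample_ids or [f"S{i + 1:03d}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=fids, columns=sids), modality, unit)
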