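"""Core in-memory containers for the subtype-discovery pipeline.

The pipeline operates on feature-by-sample expression matrices (counts per
million for miRNA, transcripts per million for mRNA) together with a
per-sample clinical table carrying the binary post-surgical outcome
(1 = seizure recurrence, 0 = seizure freedom), the adjustment covariates,
the processing batch, and which assay modalities were measured for each
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("blood_mirna", "blood_mrna", "brain_mirna", "brain_mrna")

#: Pathology categories of the cohort; the first level is the dummy-coding
#: reference (most frequent category).
PATHOLOGY_LEVELS = (
    "hippocampal sclerosis",
    "malformations of cortical development",
    "no lesion",
    "other",
)

UNITS = ("cpm", "tpm", "scaled")


class ParameterError(ValueError):
    """Invalid user-supplied parameter; the message names the field."""


@dataclass
class ExpressionMatrix:
    """A feature x sample numeric expression matrix.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.
    modality
        One of :data:`MODALITIES`.
    unit
        ``"cpm"``/``"tpm"`` for raw quantifications, ``"scaled"`` after
        standardization.
    """

    values: pd.DataFrame
    modality: str
    unit: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ParameterError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.unit not in UNITS:
            raise ParameterError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression values must be numeric")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.modality, self.unit)


@dataclass
class CohortMetadata:
    """Per-sample outcome, covariates, batch and modality availability.

    ``table`` is indexed by sample id with columns ``outcome`` (0/1),
    ``sex`` (0/1), ``pathology`` (one of :data:`PATHOLOGY_LEVELS`),
    ``surgical_side`` (1 = dominant hemisphere), ``epilepsy_duration``
    (years), ``batch``, and one boolean ``has_<modality>`` column per
    modality.
    """

    table: pd.DataFrame
    required = ("outcome", "sex", "pathology", "surgical_side", "epilepsy_duration", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.required if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in metadata")
        bad = set(self.table["outcome"]) - {0, 1}
        if bad:
            raise ValueError(f"outcome must be 0/1, found {sorted(bad)}")
        bad = set(self.table["pathology"]) - set(PATHOLOGY_LEVELS)
        if bad:
            raise ValueError(
                f"unknown pathology {sorted(bad)}; allowed: {list(PATHOLOGY_LEVELS)}"
            )
        if (self.table["epilepsy_duration"] < 0).any():
            raise ValueError("epilepsy_duration must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with(self, *modalities: str) -> list[str]:
        """Sample ids measured in every one of the given modalities."""
        mask = pd.Series(True, index=self.table.index)
        for m in modalities:
            col = f"has_{m}"
            if col not in self.table.columns:
                raise ValueError(f"metadata lacks availability column {col!r}")
            mask &= self.table[col].astype(bool)
        return list(self.table.index[mask])

    def outcomes(self, sample_ids=None) -> pd.Series:
        if sample_ids is None:
            return self.table["outcome"]
        return self.table.loc[list(sample_ids), "outcome"]
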