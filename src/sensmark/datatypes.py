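"""Core domain types shared by every analysis stage.

The pipeline operates on baseline (pre-treatment) genomics matrices of three
kinds — log2 gene expression, copy number (ordinal loss/normal/gain codes or
continuous log-ratios) and binary somatic mutation status — together with a
Sensitive/Resistant group assignment derived from drug IC50 values, and a
clinical annotation table whose variables are explicitly typed as continuous,
categorical or survival time/event pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

log = logging.getLogger("sensmark")

SENSITIVE = "Sensitive"
RESISTANT = "Resistant"

#: Default IC50 dichotomization threshold, micromolar.
DEFAULT_IC50_THRESHOLD_UM = 1.0

ORDINAL_CN_CODES = (-1, 0, 1)  # loss / normal / gain


class DataType(str, Enum):
    EXPRESSION = "expression"
    COPY_NUMBER = "copy_number"
    MUTATION = "mutation"


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass
class GenomicsMatrix:
    """A features x samples matrix of one genomics data type.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  Mutation matrices must be binary {0, 1}; ordinal copy-number
    matrices use {-1, 0, +1}; expression is real-valued log2 scale and may
    contain NaN (genes with NaN are dropped, with a logged count, before any
    statistical engine runs).
    """

    data_type: DataType
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.data_type = DataType(self.data_type)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.values.to_numpy()
        if self.data_type is DataType.MUTATION:
            if np.isnan(vals).any():
                raise ValidationError("mutation matrix contains missing values")
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"mutation value {vals[g, s]!r} not in {{0,1}} "
                    f"at gene {idx[g]!r}, sample {cols[s]!r}"
                )
            self.values = self.values.astype(np.int8)
        elif self.data_type is DataType.COPY_NUMBER:
            if np.isnan(vals).any():
                raise ValidationError("copy-number matrix contains missing values")
            if self.is_ordinal_cn:
                okay = np.isin(vals, ORDINAL_CN_CODES) | ~np.isclose(vals, np.round(vals))
                # integer-valued but outside the ordinal codes is invalid
                bad = ~okay
                if bad.any():
                    g, s = np.argwhere(bad)[0]
                    raise ValidationError(
                        f"ordinal copy-number value {vals[g, s]!r} not in "
                        f"{{-1,0,+1}} at gene {idx[g]!r}, sample {cols[s]!r}"
                    )

    @property
    def is_ordinal_cn(self) -> bool:
        """True when a copy-number matrix holds only integer codes."""
        if self.data_type is not DataType.COPY_NUMBER:
            return False
        vals = self.values.to_numpy(float)
        return bool(np.isclose(vals, np.round(vals)).all())

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, genes) -> "GenomicsMatrix":
        return GenomicsMatrix(self.data_type, self.values.loc[list(genes)])

    def subset_samples(self, samples) -> "GenomicsMatrix":
        return GenomicsMatrix(self.data_type, self.values[list(samples)])

    def drop_na_features(self) -> "GenomicsMatrix":
        """Drop genes with any missing value, logging the count."""
        mask = self.values.isna().any(axis=1)
        n = int(mask.sum())
        if n:
            log.warning("dropping %d gene(s) with missing values", n)
            return GenomicsMatrix(self.data_type, self.values.loc[~mask])
        return self


@dataclass
class SensitivityTable:
    """Per-sample IC50 readouts in micromolar."""

    ic50_um: pd.Series  # index: sample_id

    def __post_init__(self) -> None:
        if self.ic50_um.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sensitivity table")
        vals = self.ic50_um.astype(float)
        if (vals <= 0).any() or vals.isna().any():
            bad = vals.index[(vals <= 0) | vals.isna()].tolist()
            raise ValidationError(f"non-positive or missing IC50 for samples: {bad}")
        self.ic50_um = vals


@dataclass
class GroupLabels:
    """Sensitive/Resistant assignment, one label per sample."""

    labels: pd.Series  # index: sample_id, values in {Sensitive, Resistant}

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate sample ids in group labels")
        bad = set(self.labels.unique()) - {SENSITIVE, RESISTANT}
        if bad:
            raise ValidationError(f"labels must be Sensitive/Resistant, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.index.tolist()

    @property
    def sensitive_ids(self) -> list[str]:
        return self.labels.index[self.labels == SENSITIVE].tolist()

    @property
    def resistant_ids(self) -> list[str]:
        return self.labels.index[self.labels == RESISTANT].tolist()

    def for_samples(self, sample_ids) -> "GroupLabels":
        present = [s for s in sample_ids if s in self.labels.index]
        return GroupLabels(self.labels.loc[present])

    def swapped(self) -> "GroupLabels":
        return GroupLabels(
            self.labels.map({SENSITIVE: RESISTANT, RESISTANT: SENSITIVE})
        )


def label_samples_by_ic50(
    table: SensitivityTable, threshold_um: float = DEFAULT_IC50_THRESHOLD_UM
) -> GroupLabels:
    """Dichotomize IC50 values into Sensitive / Resistant groups.

    A sample is Sensitive when its IC50 is strictly below ``threshold_um``
    (default 1 µM); samples exactly at the threshold are called Resistant
    (conservative boundary rule).
    """
    if threshold_um <= 0:
        raise ValidationError("threshold_um must be positive")
    lab = pd.Series(
        np.where(table.ic50_um < threshold_um, SENSITIVE, RESISTANT),
        index=table.ic50_um.index,
        name="label",
    )
    return GroupLabels(lab)


class VariableType(str, Enum):
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    SURVIVAL_TIME = "survival_time"
    SURVIVAL_EVENT = "survival_event"


@dataclass
class ClinicalAnnotationTable:
    """Sample x variable clinical annotations with explicit variable typing.

    ``variable_types`` maps each column of ``data`` to a :class:`VariableType`.
    A survival_time variable ``X`` pairs with the survival_event variable
    named ``X_event`` (or, when exactly one event column exists, that one).
    Types are never inferred silently.
    """

    data: pd.DataFrame  # index: sample_id
    variable_types: dict[str, VariableType] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variable_types = {
            k: VariableType(v) for k, v in self.variable_types.items()
        }
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        missing = set(self.data.columns) - set(self.variable_types)
        if missing:
            raise ValidationError(f"variables without a declared type: {sorted(missing)}")
        for name, vtype in self.variable_types.items():
            if name not in self.data.columns:
                raise ValidationError(f"declared variable {name!r} absent from table")
            col = self.data[name]
            if vtype is VariableType.SURVIVAL_TIME:
                vals = pd.to_numeric(col, errors="coerce").dropna()
                if (vals < 0).any():
                    raise ValidationError(f"negative survival time in {name!r}")
            elif vtype is VariableType.SURVIVAL_EVENT:
                vals = pd.to_numeric(col, errors="coerce").dropna()
                if not vals.isin([0, 1]).all():
                    raise ValidationError(f"survival event {name!r} not in {{0,1}}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def event_column_for(self, time_var: str) -> str:
        """Resolve the event column paired with a survival_time variable."""
        cand = f"{time_var}_event"
        if self.variable_types.get(cand) is VariableType.SURVIVAL_EVENT:
            return cand
        events = [
            n for n, t in self.variable_types.items()
            if t is VariableType.SURVIVAL_EVENT
        ]
        if len(events) == 1:
            return events[0]
        raise ValidationError(
            f"cannot pair survival_time {time_var!r} with an event column"
        )
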