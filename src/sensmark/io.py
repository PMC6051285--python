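"""Tab-delimited readers and writers for every interchange table.

All files are plain TSV.  Genomics matrices have ``GeneSymbol`` in cell (1,1),
sample ids as the remaining header fields and one gene per row.  Result tables
(markers, predictions, associations) round-trip losslessly through the
matching reader at full float precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalAnnotationTable,
    DataType,
    GenomicsMatrix,
    GroupLabels,
    SensitivityTable,
    ValidationError,
    VariableType,
)

log = logging.getLogger("sensmark")

GENE_HEADER = "GeneSymbol"


class FormatError(ValueError):
    """Raised when a file does not match the expected TSV dialect."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=["", "NA", "NaN", "nan"])


def read_genomics_table(path, data_type: DataType | str) -> GenomicsMatrix:
    """Read a genes-in-rows TSV matrix and validate it for ``data_type``.

    Duplicate gene rows collapse to the row with the highest variance across
    samples (a warning is logged).  Malformed numeric cells are rejected.
    """
    data_type = DataType(data_type)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != GENE_HEADER:
        raise FormatError(
            f"{path}: first header field must be {GENE_HEADER!r}, "
            f"got {header[0] if header else ''!r}"
        )
    if len(header) < 2:
        raise FormatError(f"{path}: expected a gene column plus >=1 sample column")
    dup_samples = pd.Index(header[1:])
    if dup_samples.has_duplicates:
        dups = dup_samples[dup_samples.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample header(s): {dups}")
    raw = _read_tsv(path)
    try:
        mat = raw.set_index(GENE_HEADER).astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric cell ({exc})") from exc
    if mat.index.has_duplicates:
        # keep the highest-variance duplicate row (common microarray convention)
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        log.warning("%s: collapsing duplicate gene rows by max variance: %s", path, dups)
        variances = mat.var(axis=1).to_numpy()
        mat = mat.assign(_var=variances)
        mat = (
            mat.sort_values("_var", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_var")
        )
        mat = mat.loc[~mat.index.duplicated()]
        mat = mat.loc[[g for g in dict.fromkeys(raw[GENE_HEADER]) if g in mat.index]]
    if data_type in (DataType.MUTATION, DataType.COPY_NUMBER) and mat.isna().any().any():
        raise ValidationError(f"{path}: missing values not allowed for {data_type.value}")
    mat.index.name = None
    return GenomicsMatrix(data_type, mat)


def write_genomics_table(matrix: GenomicsMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = GENE_HEADER
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sensitivity_table(path) -> SensitivityTable:
    raw = _read_tsv(path)
    if list(raw.columns[:2]) != ["sample_id", "ic50_um"]:
        raise FormatError(f"{path}: expected columns sample_id, ic50_um")
    ser = pd.Series(
        pd.to_numeric(raw["ic50_um"], errors="coerce").to_numpy(),
        index=raw["sample_id"].tolist(),
        name="ic50_um",
    )
    return SensitivityTable(ser)


def write_sensitivity_table(table: SensitivityTable, path) -> None:
    df = table.ic50_um.rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_label_table(path) -> GroupLabels:
    raw = _read_tsv(path)
    if list(raw.columns[:2]) != ["sample_id", "label"]:
        raise FormatError(f"{path}: expected columns sample_id, label")
    return GroupLabels(pd.Series(raw["label"].tolist(), index=raw["sample_id"].tolist(),
                                 name="label"))


def write_label_table(labels: GroupLabels, path) -> None:
    labels.labels.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_clinical_table(path, types_path) -> ClinicalAnnotationTable:
    """Read a samples-in-rows annotation TSV plus its sidecar type declaration."""
    raw = _read_tsv(path)
    if raw.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be sample_id")
    data = raw.set_index("sample_id")
    data.index.name = None
    types_raw = _read_tsv(types_path)
    if list(types_raw.columns[:2]) != ["variable", "type"]:
        raise FormatError(f"{types_path}: expected columns variable, type")
    vtypes = {
        r.variable: VariableType(r.type) for r in types_raw.itertuples(index=False)
    }
    for name, vtype in vtypes.items():
        if name not in data.columns:
            continue
        if vtype in (VariableType.CONTINUOUS, VariableType.SURVIVAL_TIME,
                     VariableType.SURVIVAL_EVENT):
            data[name] = pd.to_numeric(data[name], errors="coerce")
    return ClinicalAnnotationTable(data, vtypes)


def write_clinical_table(table: ClinicalAnnotationTable, path, types_path) -> None:
    table.data.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    types_df = pd.DataFrame(
        {
            "variable": list(table.variable_types),
            "type": [t.value for t in table.variable_types.values()],
        }
    )
    types_df.to_csv(types_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables: written with full float precision so round-trips are lossless

def _write_result(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_marker_table(table: pd.DataFrame, path) -> None:
    _write_result(table, path)


def read_marker_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df


def write_prediction_table(table: pd.DataFrame, path) -> None:
    _write_result(table, path)


def read_prediction_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_association_table(table: pd.DataFrame, path) -> None:
    _write_result(table, path)


def read_association_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
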