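"""Transfer of a biomarker signature to a clinical cohort by random forest.

A signature (gene list) learned on a training dataset (cell lines in the
translational workflow, a clinical cohort in the clinical workflow) is used
to train an ensemble of classification trees on the training samples'
Sensitive/Resistant labels; every clinical sample is then assigned the label
voted by the majority of trees, with the Sensitive vote fraction reported.

Because cell-line and tumor expression live on different scales, each
signature gene is by default z-scored within each dataset separately before
training/prediction (``harmonize='zscore'``); binary and ordinal features
pass through unchanged.  Signature genes absent from the target matrix are
dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datatypes import RESISTANT, SENSITIVE, DataType, GenomicsMatrix, GroupLabels

log = logging.getLogger("sensmark")

#: ensemble size used for real runs; tests use a small odd count instead
DEFAULT_N_TREES = 100_000

PREDICTION_COLUMNS = ["sample_id", "predicted_label", "vote_fraction_sensitive", "n_trees"]


@dataclass
class SignatureSpec:
    genes: list[str]
    data_type: DataType
    harmonize: str = "zscore"  # or "none"

    def __post_init__(self) -> None:
        self.data_type = DataType(self.data_type)
        if self.harmonize not in ("zscore", "none"):
            raise ValueError("harmonize must be 'zscore' or 'none'")
        if not self.genes:
            raise ValueError("empty signature")


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def harmonize_features(
    train: GenomicsMatrix, target: GenomicsMatrix, signature: SignatureSpec
) -> tuple[GenomicsMatrix, GenomicsMatrix, list[str]]:
    """Restrict both matrices to the shared signature genes and harmonize.

    Returns (train', target', dropped) where dropped lists signature genes
    missing from either matrix.  For expression and continuous copy number,
    each retained gene is z-scored within each dataset separately; mutation
    and ordinal copy-number values pass through.
    """
    if train.data_type is not target.data_type:
        raise ValueError("train and target matrices must share a data type")
    shared = [g for g in signature.genes
              if g in train.values.index and g in target.values.index]
    dropped = [g for g in signature.genes if g not in shared]
    if not shared:
        raise ValueError("no signature genes shared with the target matrix")
    if dropped:
        log.warning("signature genes absent from a matrix, dropped: %s", dropped)
    tr = train.values.loc[shared]
    tg = target.values.loc[shared]
    continuous = signature.data_type is DataType.EXPRESSION or (
        signature.data_type is DataType.COPY_NUMBER and not train.is_ordinal_cn
    )
    if signature.harmonize == "zscore" and continuous:
        tr = _zscore_rows(tr)
        tg = _zscore_rows(tg)
    return (
        GenomicsMatrix(train.data_type, tr),
        GenomicsMatrix(target.data_type, tg),
        dropped,
    )


def train_forest(
    train: GenomicsMatrix,
    labels: GroupLabels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the voting ensemble on the signature-restricted training matrix."""
    lab = labels.for_samples(train.sample_ids)
    if len(set(lab.labels)) < 2:
        raise ValueError("training labels contain a single class")
    if train.n_features < 1:
        raise ValueError("no features to train on")
    X = train.values[lab.sample_ids].to_numpy(float).T
    y = lab.labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
    )
    forest.fit(X, y)
    forest.feature_names_ = list(train.feature_ids)
    return forest


def predict_clinical(
    forest: RandomForestClassifier, target: GenomicsMatrix
) -> pd.DataFrame:
    """Majority-vote prediction per clinical sample.

    vote_fraction_sensitive is the fraction of trees whose own prediction is
    Sensitive; the label is Sensitive iff that fraction exceeds 0.5 (an exact
    tie is called Resistant).
    """
    expected = getattr(forest, "feature_names_", None)
    if expected is not None and list(target.feature_ids) != list(expected):
        raise ValueError(
            f"target features {target.feature_ids} do not match the forest's "
            f"training features {list(expected)}"
        )
    X = target.values.to_numpy(float).T
    classes = list(forest.classes_)
    s_index = classes.index(SENSITIVE)
    votes = np.zeros(X.shape[0])
    for tree in forest.estimators_:
        proba = tree.predict_proba(X)
        votes += (np.argmax(proba, axis=1) == s_index)
    frac = votes / len(forest.estimators_)
    labels = np.where(frac > 0.5, SENSITIVE, RESISTANT)
    return pd.DataFrame(
        {
            "sample_id": target.sample_ids,
            "predicted_label": labels,
            "vote_fraction_sensitive": frac,
            "n_trees": len(forest.estimators_),
        }
    )


def predictions_to_labels(predictions: pd.DataFrame) -> GroupLabels:
    """View a prediction table as GroupLabels for the association stage."""
    return GroupLabels(
        pd.Series(
            predictions["predicted_label"].to_numpy(),
            index=predictions["sample_id"].to_numpy(),
            name="label",
        )
    )
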