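"""Orchestration of the translational and clinical workflows.

Both workflows run the same stage chain — stepwise filtering, the selected
marker engines, marker filtering into a signature, harmonization + random
forest transfer, clinical association ranking and cluster exports — and
differ only in the training source: a cell-line panel (translational) or a
labeled clinical cohort (clinical).  Every run writes each intermediate
table plus a JSON manifest recording versions, seed, the config echo and
per-stage counts.  When several engines are selected each yields its own
signature and downstream branch; signatures are never merged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .associations import associate_all
from .clustering import cluster, heatmap_data, volcano_data
from .datatypes import (
    ClinicalAnnotationTable,
    DataType,
    GenomicsMatrix,
    GroupLabels,
)
from .filtering import FilterConfig, stepwise_filter
from .markers import (
    anova_markers,
    filter_markers,
    hypergeometric_markers,
    moderated_t_markers,
    odds_ratio_markers,
)
from .stability import MIN_GROUP_SIZE, EnetConfig, filter_enet_markers, stability_elastic_net
from .transfer import (
    SignatureSpec,
    harmonize_features,
    predict_clinical,
    predictions_to_labels,
    train_forest,
)

log = logging.getLogger("sensmark")

ENGINES = ("anova", "moderated_t", "hypergeometric", "odds_ratio", "elastic_net")

#: which data types each engine accepts
ENGINE_DTYPES = {
    "anova": (DataType.EXPRESSION, DataType.COPY_NUMBER),
    "moderated_t": (DataType.EXPRESSION,),
    "hypergeometric": (DataType.MUTATION,),
    "odds_ratio": (DataType.MUTATION,),
    "elastic_net": (DataType.EXPRESSION, DataType.COPY_NUMBER, DataType.MUTATION),
}


class StageError(RuntimeError):
    """A stage precondition failed; carries the stage name and reason."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {reason}")


@dataclass
class RunConfig:
    workflow: str = "translational"
    engines: tuple[str, ...] = ("anova",)
    expression_floor: float | None = None
    correlation_cutoff: float = 0.1
    marker_p_max: float = 1e-4
    marker_effect_min_abs: float = 1.5
    mutation_p_max: float = 0.1
    mutation_log10_or_min: float = 1.0
    enet_frequency_min_pct: float = 50.0
    enet: EnetConfig | None = None
    n_trees: int = 2001
    harmonize: str = "zscore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in ("translational", "clinical"):
            raise ValueError("workflow must be 'translational' or 'clinical'")
        bad = set(self.engines) - set(ENGINES)
        if bad:
            raise ValueError(f"unknown engine(s): {sorted(bad)}")


def _branch_seed(base_seed: int, *tags: str) -> int:
    """Deterministic per-branch seed derived from the single run seed."""
    digest = hashlib.sha256(("/".join(tags)).encode()).digest()
    tag_int = int.from_bytes(digest[:4], "little")
    h = np.random.default_rng([int(base_seed), tag_int])
    return int(h.integers(0, 2**31 - 1))


def _run_engine(engine, matrix, labels, config: RunConfig):
    if engine == "anova":
        return anova_markers(matrix, labels)
    if engine == "moderated_t":
        return moderated_t_markers(matrix, labels)
    if engine == "hypergeometric":
        return hypergeometric_markers(matrix, labels)
    if engine == "odds_ratio":
        return odds_ratio_markers(matrix, labels)
    enet_cfg = replace(
        config.enet or EnetConfig(seed=0),
        seed=_branch_seed(config.seed, "enet", matrix.data_type.value),
    )
    return stability_elastic_net(matrix, labels, enet_cfg)


def _signature_from_markers(engine, table, config: RunConfig, data_type):
    if engine == "elastic_net":
        return filter_enet_markers(table, config.enet_frequency_min_pct)
    if engine == "odds_ratio":
        # the |log10 OR| cut only makes sense on the odds-ratio effect scale
        return filter_markers(table, config.mutation_p_max, config.mutation_log10_or_min)
    if data_type is DataType.MUTATION:
        return filter_markers(table, config.mutation_p_max, 0.0)
    return filter_markers(table, config.marker_p_max, config.marker_effect_min_abs)


def run_workflow(
    train_matrices: dict[str, GenomicsMatrix],
    train_labels: GroupLabels,
    target_matrices: dict[str, GenomicsMatrix],
    clinical: ClinicalAnnotationTable | None,
    config: RunConfig,
    out_dir,
) -> dict:
    """Execute the full stage chain and write all outputs under ``out_dir``.

    Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sensmark",
        "version": __version__,
        "workflow": config.workflow,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": [],
        "warnings": [],
    }
    n_sens = len(train_labels.sensitive_ids)
    n_res = len(train_labels.resistant_ids)
    if n_sens == 0 or n_res == 0:
        raise StageError("labeling", "both Sensitive and Resistant training groups required")
    manifest["n_train_sensitive"] = n_sens
    manifest["n_train_resistant"] = n_res

    filter_cfg = FilterConfig(config.expression_floor, config.correlation_cutoff)
    filtered: dict[str, GenomicsMatrix] = {}
    for dtype_name, matrix in train_matrices.items():
        try:
            fmat, report = stepwise_filter(matrix, train_labels, filter_cfg)
        except ValueError as exc:
            raise StageError("filtering", str(exc)) from exc
        filtered[dtype_name] = fmat
        report.to_frame().to_csv(out / f"filter_report_{dtype_name}.tsv",
                                 sep="\t", index=False)
        manifest["stages"].append(
            {"stage": "filter", "data_type": dtype_name,
             "n_input": report.n_input, "n_retained": report.n_retained}
        )

    branches = 0
    for engine in config.engines:
        for dtype in ENGINE_DTYPES[engine]:
            dtype_name = dtype.value
            if dtype_name not in filtered:
                continue
            fmat = filtered[dtype_name]
            if fmat.n_features == 0:
                manifest["warnings"].append(
                    f"{engine}/{dtype_name}: no features survived filtering; skipped"
                )
                continue
            if engine == "elastic_net" and min(n_sens, n_res) < MIN_GROUP_SIZE:
                manifest["warnings"].append(
                    f"elastic_net/{dtype_name}: skipped, needs >= {MIN_GROUP_SIZE} "
                    f"samples per group (got {n_sens}/{n_res})"
                )
                continue
            try:
                table = _run_engine(engine, fmat, train_labels, config)
            except (ValueError, TypeError) as exc:
                raise StageError(f"markers:{engine}:{dtype_name}", str(exc)) from exc
            io.write_marker_table(table, out / f"markers_{engine}_{dtype_name}.tsv")
            if engine in ("anova", "moderated_t"):
                io.write_marker_table(
                    volcano_data(table), out / f"volcano_{engine}_{dtype_name}.tsv"
                )
            signature_table = _signature_from_markers(engine, table, config, dtype)
            io.write_marker_table(
                signature_table, out / f"signature_{engine}_{dtype_name}.tsv"
            )
            manifest["stages"].append(
                {"stage": "markers", "engine": engine, "data_type": dtype_name,
                 "n_tested": len(table), "n_signature": len(signature_table)}
            )
            if signature_table.empty:
                manifest["warnings"].append(
                    f"{engine}/{dtype_name}: empty signature; transfer skipped"
                )
                continue
            if dtype_name not in target_matrices:
                manifest["warnings"].append(
                    f"{engine}/{dtype_name}: no target matrix; transfer skipped"
                )
                continue
            genes = signature_table["gene"].tolist()
            try:
                spec = SignatureSpec(genes, dtype, config.harmonize)
                tr, tg, dropped = harmonize_features(
                    train_matrices[dtype_name], target_matrices[dtype_name], spec
                )
                forest = train_forest(
                    tr, train_labels, n_trees=config.n_trees,
                    seed=_branch_seed(config.seed, "forest", engine, dtype_name),
                )
                predictions = predict_clinical(forest, tg)
            except ValueError as exc:
                raise StageError(f"transfer:{engine}:{dtype_name}", str(exc)) from exc
            io.write_prediction_table(
                predictions, out / f"predictions_{engine}_{dtype_name}.tsv"
            )
            n_pred_s = int((predictions["predicted_label"] == "Sensitive").sum())
            manifest["stages"].append(
                {"stage": "transfer", "engine": engine, "data_type": dtype_name,
                 "n_signature_used": tg.n_features, "n_dropped_genes": len(dropped),
                 "n_predicted": len(predictions), "n_predicted_sensitive": n_pred_s}
            )
            # cluster exports on the harmonized signature matrix
            if tg.n_features >= 2 and tg.n_samples >= 2:
                feat = cluster(tg, "features")
                samp = cluster(tg, "samples")
                feat.merge_table().to_csv(
                    out / f"linkage_features_{engine}_{dtype_name}.tsv",
                    sep="\t", index=False)
                samp.merge_table().to_csv(
                    out / f"linkage_samples_{engine}_{dtype_name}.tsv",
                    sep="\t", index=False)
                hm = heatmap_data(tg)
                hm.index.name = "GeneSymbol"
                hm.to_csv(out / f"heatmap_{engine}_{dtype_name}.tsv",
                          sep="\t", float_format="%.17g")
            if clinical is None:
                manifest["warnings"].append(
                    f"{engine}/{dtype_name}: no clinical annotations; association skipped"
                )
            else:
                assoc, km_frames = associate_all(
                    clinical, predictions_to_labels(predictions)
                )
                io.write_association_table(
                    assoc, out / f"associations_{engine}_{dtype_name}.tsv"
                )
                for var, km in km_frames.items():
                    km.to_csv(out / f"km_{engine}_{dtype_name}_{var}.tsv",
                              sep="\t", index=False, float_format="%.17g")
                manifest["stages"].append(
                    {"stage": "associate", "engine": engine, "data_type": dtype_name,
                     "n_variables": len(assoc)}
                )
            branches += 1

    if branches == 0:
        manifest["warnings"].append("no engine/data-type branch completed transfer")
    manifest["n_branches"] = branches
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if echo.get("enet") is not None:
        echo["enet"] = dict(echo["enet"])
    echo["engines"] = list(config.engines)
    return echo


def run_translational(train_matrices, train_labels, target_matrices, clinical,
                      config: RunConfig, out_dir) -> dict:
    """Cell-line training cohort -> clinical target cohort."""
    config.workflow = "translational"
    return run_workflow(train_matrices, train_labels, target_matrices,
                        clinical, config, out_dir)


def run_clinical(train_matrices, train_labels, target_matrices, clinical,
                 config: RunConfig, out_dir) -> dict:
    """Labeled clinical training cohort -> second clinical cohort."""
    config.workflow = "clinical"
    return run_workflow(train_matrices, train_labels, target_matrices,
                        clinical, config, out_dir)
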