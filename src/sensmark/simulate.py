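"""Seeded generators of cell-line panels and annotated clinical cohorts.

The generators plant the structure the workflows are meant to recover:

* an amplicon-style block of genes that is jointly copy-number gained and
  log2-overexpressed in Sensitive samples (mimicking the ERBB2-amplicon
  pattern of co-amplified, co-overexpressed neighbors);
* a driver mutation carried by Sensitive lines at a configurable penetrance,
  with a configurable number of discordant Resistant carriers (the classic
  "mutated but resistant" cell line);
* clinical covariates correlated with the latent molecular profile — an
  IHC-like 0/1+/2+/3+ category, an age-like continuous shift and a survival
  difference (exponential times with a group hazard ratio and uniform
  censoring).

Tumor-scale expression deliberately sits on a different global baseline than
the cell-line panel so that cross-dataset harmonization is actually
exercised.  All outputs validate against the core domain types and are
bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalAnnotationTable,
    DataType,
    GenomicsMatrix,
    SensitivityTable,
    VariableType,
)

IHC_CATEGORIES = ("0", "1+", "2+", "3+")


@dataclass
class SimulationConfig:
    """Stated world of the simulator; every field has explicit units.

    Cell-line group sizes default to 8+8 (small screening panels; the
    elastic net needs at least 4 per group).  The amplicon shift is 3 log2
    units against unit noise SD — a strong amplification signal of the kind
    the translational workflow targets.  Clinical covariate defaults encode
    a dominant IHC 3+ enrichment, a modest ~6-year age shift and a 2-fold
    survival hazard ratio.
    """

    seed: int
    # cell-line panel
    n_sensitive: int = 8
    n_resistant: int = 8
    n_genes: int = 300
    amplicon_size: int = 10
    amplicon_expr_shift: float = 3.0      # log2 units added in gained samples
    cn_gain_prob_sensitive: float = 0.9   # per-sample whole-block gain
    cn_gain_prob_resistant: float = 0.02
    driver_penetrance: float = 1.0        # P(driver mutated | Sensitive)
    n_resistant_driver_carriers: int = 1  # discordant resistant carriers
    background_mutation_rate: float = 0.10
    noise_sd: float = 1.0                 # log2 expression noise SD
    expr_baseline_mean: float = 7.0
    # IC50 draw ranges, micromolar (log-uniform within each range)
    ic50_sensitive_range: tuple[float, float] = (0.01, 0.5)
    ic50_resistant_range: tuple[float, float] = (2.0, 30.0)
    # clinical cohort
    n_clinical: int = 120
    prevalence: float = 0.3               # fraction with the sensitive profile
    tumor_mean_shift: float = 2.0         # global log2 offset vs cell lines
    tumor_noise_scale: float = 1.5
    ihc_probs_sensitive: tuple = (0.05, 0.10, 0.10, 0.75)
    ihc_probs_resistant: tuple = (0.45, 0.30, 0.15, 0.10)
    age_mean_years: float = 60.0
    age_shift_years: float = -6.0         # added for sensitive-profile samples
    age_sd_years: float = 12.0
    survival_median_months: float = 36.0  # resistant-profile baseline
    sensitive_hazard_ratio: float = 0.5   # <1: sensitive profile lives longer
    censor_max_months: float = 72.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_sensitive", "n_resistant", "n_genes", "amplicon_size",
                     "n_clinical"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cn_gain_prob_sensitive", "cn_gain_prob_resistant",
                     "driver_penetrance", "background_mutation_rate",
                     "prevalence"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.amplicon_size >= self.n_genes:
            raise ValueError("amplicon_size must be < n_genes")

    def gene_names(self) -> list[str]:
        amp = [f"AMP{i:02d}" for i in range(1, self.amplicon_size + 1)]
        n_null = self.n_genes - self.amplicon_size
        null = [f"GENE{i:04d}" for i in range(1, n_null + 1)]
        return amp + null


def _loguniform(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _molecular_layer(rng, config: SimulationConfig, profile: np.ndarray,
                     sample_ids, mean_shift: float, noise_scale: float,
                     gain_probs: tuple[float, float]):
    """Expression / CN / mutation matrices for samples with a 0/1 profile."""
    genes = config.gene_names()
    n_amp = config.amplicon_size
    n = len(sample_ids)
    gene_means = rng.normal(config.expr_baseline_mean + mean_shift, 1.0,
                            len(genes))
    expr = gene_means[:, None] + rng.normal(
        0.0, config.noise_sd * noise_scale, (len(genes), n)
    )
    # whole-block amplicon gain is a per-sample event
    p_gain = np.where(profile == 1, gain_probs[0], gain_probs[1])
    gained = rng.random(n) < p_gain
    expr[:n_amp, gained] += config.amplicon_expr_shift
    cn = np.zeros((len(genes), n), dtype=int)
    cn[:n_amp, gained] = 1
    # sparse background CN noise outside the amplicon block
    noise_cn = rng.random((len(genes) - n_amp, n))
    cn[n_amp:][noise_cn < 0.03] = -1
    cn[n_amp:][noise_cn > 0.97] = 1
    mut = (rng.random((len(genes), n)) <
           config.background_mutation_rate).astype(int)
    frames = {}
    for name, arr in (("expression", expr), ("copy_number", cn), ("mutation", mut)):
        frames[name] = pd.DataFrame(arr, index=genes, columns=sample_ids)
    return frames, gained


def generate_cell_line_panel(
    config: SimulationConfig,
) -> tuple[GenomicsMatrix, GenomicsMatrix, GenomicsMatrix, SensitivityTable]:
    """Simulate a Sensitive/Resistant cell-line panel.

    Returns (expression, copy_number, mutation, sensitivity) with the
    planted amplicon, the driver mutation (gene ``DRIVER``) and IC50 values
    drawn below/above 1 µM for the two groups.
    """
    rng = np.random.default_rng([int(config.seed), 11])
    ns, nr = config.n_sensitive, config.n_resistant
    ids = [f"CL_S{i:02d}" for i in range(1, ns + 1)] + [
        f"CL_R{i:02d}" for i in range(1, nr + 1)
    ]
    profile = np.array([1] * ns + [0] * nr)
    frames, _ = _molecular_layer(
        rng, config, profile, ids, mean_shift=0.0, noise_scale=1.0,
        gain_probs=(config.cn_gain_prob_sensitive, config.cn_gain_prob_resistant),
    )
    mut = frames["mutation"]
    driver_row = pd.Series(0, index=mut.columns, name="DRIVER")
    carriers = rng.random(ns) < config.driver_penetrance
    driver_row.iloc[:ns] = carriers.astype(int)
    k = min(config.n_resistant_driver_carriers, nr)
    if k > 0:
        picks = rng.choice(np.arange(ns, ns + nr), size=k, replace=False)
        driver_row.iloc[picks] = 1
    mut = pd.concat([pd.DataFrame([driver_row]), mut])
    ic50 = np.concatenate(
        [
            _loguniform(rng, *config.ic50_sensitive_range, ns),
            _loguniform(rng, *config.ic50_resistant_range, nr),
        ]
    )
    sens = SensitivityTable(pd.Series(ic50, index=ids, name="ic50_um"))
    return (
        GenomicsMatrix(DataType.EXPRESSION, frames["expression"]),
        GenomicsMatrix(DataType.COPY_NUMBER, frames["copy_number"]),
        GenomicsMatrix(DataType.MUTATION, mut),
        sens,
    )


def generate_clinical_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, GenomicsMatrix], ClinicalAnnotationTable, pd.Series]:
    """Simulate an annotated clinical cohort on a tumor-scale baseline.

    A round(prevalence x n_clinical) subset of samples carries the sensitive
    molecular profile; their annotations show the configured IHC enrichment,
    age shift and survival advantage.  Returns (matrices, annotations,
    latent_labels); latent labels are for accuracy scoring only and are
    never written into cohort files.
    """
    rng = np.random.default_rng([int(config.seed), 23])
    n = config.n_clinical
    ids = [f"TUM{i:04d}" for i in range(1, n + 1)]
    n_pos = int(round(config.prevalence * n))
    profile = np.zeros(n, dtype=int)
    profile[rng.permutation(n)[:n_pos]] = 1
    # profile carriers are defined by carrying the molecular profile, so the
    # amplicon gain and driver mutation are deterministic given profile=1;
    # probabilistic penetrance belongs to the IC50-defined cell-line groups
    frames, _ = _molecular_layer(
        rng, config, profile, ids,
        mean_shift=config.tumor_mean_shift,
        noise_scale=config.tumor_noise_scale,
        gain_probs=(1.0, config.cn_gain_prob_resistant),
    )
    mut = frames["mutation"]
    driver_row = pd.Series(
        np.where(profile == 1, 1,
                 (rng.random(n) < 0.02).astype(int)).astype(int),
        index=mut.columns, name="DRIVER",
    )
    mut = pd.concat([pd.DataFrame([driver_row]), mut])
    matrices = {
        "expression": GenomicsMatrix(DataType.EXPRESSION, frames["expression"]),
        "copy_number": GenomicsMatrix(DataType.COPY_NUMBER, frames["copy_number"]),
        "mutation": GenomicsMatrix(DataType.MUTATION, mut),
    }
    # clinical covariates driven by the latent profile
    ihc = np.empty(n, dtype=object)
    for i in range(n):
        probs = (config.ihc_probs_sensitive if profile[i] == 1
                 else config.ihc_probs_resistant)
        ihc[i] = rng.choice(IHC_CATEGORIES, p=np.asarray(probs, float))
    age = rng.normal(
        config.age_mean_years + config.age_shift_years * profile,
        config.age_sd_years,
    )
    base_hazard = np.log(2.0) / config.survival_median_months
    hazard = base_hazard * np.where(profile == 1, config.sensitive_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_max_months, n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    data = pd.DataFrame(
        {
            "ihc_category": ihc,
            "age_years": age,
            "os_months": time,
            "os_months_event": event,
        },
        index=ids,
    )
    clinical = ClinicalAnnotationTable(
        data,
        {
            "ihc_category": VariableType.CATEGORICAL,
            "age_years": VariableType.CONTINUOUS,
            "os_months": VariableType.SURVIVAL_TIME,
            "os_months_event": VariableType.SURVIVAL_EVENT,
        },
    )
    latent = pd.Series(
        np.where(profile == 1, "Sensitive", "Resistant"), index=ids, name="latent"
    )
    return matrices, clinical, latent
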