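"""Synthetic expression cohorts with the structure the pipeline assumes.

Three generators cover the analysis' input regimes:

``generate_cohort``
    A pre/post exercise cohort.  Model genes are bimodal: each Boolean
    cluster draws an independent Bernoulli(0.5) latent state per sample
    (low or high mode) shared by the cluster's genes, plus Gaussian noise —
    the step structure StepMiner presupposes and the within-cluster
    correlation Boolean equivalence detects.  Post samples receive an
    additive log2 shift on one arm's genes; the ``shift`` parameter is read
    on the *composite-score* scale (negative = M1 direction = the immediate
    post-exercise surge; positive = M2 direction = long-term training), so
    the expression-level offset is ``shift × sign(arm weight)``.  Null genes
    are unimodal noise.  Missing cells, entirely-absent model genes and
    duplicated probe rows are injected at configurable rates.

``generate_polarized_set``
    Samples labeled M1/M2 with arm-consistent expression (M1-arm clusters
    high in M1 samples and low in M2 samples, and vice versa) — the regime
    of pooled polarized-macrophage validation data, where cross-arm
    opposite Boolean relations exist by construction.

``generate_signature_screen_cohort``
    Unimodal genes, a subset carrying a ± effect in post samples, for
    per-gene AUC screening experiments with known ground truth.

Default parameters are the package's reference study conditions (documented
in the methods note): a model mirroring the 338-gene polarization model's
shape (12 M1 clusters + 72 M2 clusters of 4 genes → 48 M1 / 288 M2 genes,
per-arm-normalized weights), 40+40 samples, low/high modes at 4/7 log2 and
noise SD 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleAnnotation, write_annotation, write_matrix
from .polarization_score import PolarizationModel, write_model

log = logging.getLogger("macpolar")


def default_model_clusters() -> tuple[tuple[str, int, float], ...]:
    """Cluster layout mirroring the full polarization model's shape.

    12 M1 clusters and 72 M2 clusters of 4 genes each (48 M1 / 288 M2
    genes); weights are normalized per arm (−1/12 and +1/72) so each arm
    contributes equally to the composite score.
    """
    m1 = tuple(("M1", 4, -1.0 / 12) for _ in range(12))
    m2 = tuple(("M2", 4, 1.0 / 72) for _ in range(72))
    return m1 + m2


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic pre/post cohort (see module docstring)."""

    n_pre: int = 40
    n_post: int = 40
    clusters: tuple[tuple[str, int, float], ...] = field(default_factory=default_model_clusters)
    low_mean: float = 4.0
    high_mean: float = 7.0
    noise_sd: float = 0.5
    shift: float = 0.0
    shift_arm: str = "M1"
    missing_cell_fraction: float = 0.0
    missing_gene_fraction: float = 0.0
    probe_dup_fraction: float = 0.0
    n_null_genes: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_pre <= 0 or self.n_post <= 0:
            raise ValueError("sample counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for frac in (self.missing_cell_fraction, self.missing_gene_fraction,
                     self.probe_dup_fraction):
            if not 0.0 <= frac < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        if self.shift_arm not in ("M1", "M2"):
            raise ValueError("shift_arm must be 'M1' or 'M2'")
        if not self.clusters:
            raise ValueError("at least one cluster is required")
        for arm, n_genes, weight in self.clusters:
            if arm not in ("M1", "M2") or n_genes <= 0 or weight == 0:
                raise ValueError(f"invalid cluster spec ({arm}, {n_genes}, {weight})")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    matrix: ExpressionMatrix
    annotation: SampleAnnotation
    truth_model: PolarizationModel
    truth_shift: float
    config: SyntheticConfig


def _truth_model(config: SyntheticConfig) -> tuple[PolarizationModel, pd.DataFrame]:
    """Model entries + per-gene layout table (cluster index, arm, weight)."""
    rows = []
    arm_counter = {"M1": 0, "M2": 0}
    for arm, n_genes, weight in config.clusters:
        arm_counter[arm] += 1
        cluster_id = f"{arm}C{arm_counter[arm]:02d}"
        for g in range(1, n_genes + 1):
            rows.append({"gene": f"{cluster_id}G{g}", "cluster_id": cluster_id,
                         "arm": arm, "weight": weight})
    layout = pd.DataFrame(rows)
    model = PolarizationModel(layout.copy(), name="synthetic_truth",
                              source="generate_cohort")
    return model, layout


def _inject_artifacts(values: pd.DataFrame, gene_of_row: pd.Series,
                      layout: pd.DataFrame, config: SyntheticConfig,
                      rng: np.random.Generator, regen_noise) -> ExpressionMatrix:
    """Apply probe duplication, whole-gene dropout and missing cells."""
    model_genes = layout["gene"].tolist()
    if config.probe_dup_fraction > 0 and model_genes:
        n_dup = int(round(config.probe_dup_fraction * len(model_genes)))
        dup_genes = list(rng.choice(model_genes, size=n_dup, replace=False)) if n_dup else []
        for gene in dup_genes:
            # second probe: same latent signal, fresh measurement noise
            base = values.loc[gene].to_numpy() - regen_noise[gene]
            probe = base + rng.normal(0.0, config.noise_sd, values.shape[1])
            values.loc[f"{gene}_p2"] = probe
            gene_of_row.loc[f"{gene}_p2"] = gene
    if config.missing_gene_fraction > 0 and model_genes:
        n_drop = int(round(config.missing_gene_fraction * len(model_genes)))
        drop = list(rng.choice(model_genes, size=n_drop, replace=False)) if n_drop else []
        drop_rows = [r for r in values.index
                     if r in drop or (r.endswith("_p2") and r[:-3] in drop)]
        values = values.drop(index=drop_rows)
        gene_of_row = gene_of_row.drop(index=drop_rows)
    if config.missing_cell_fraction > 0:
        mask = rng.random(values.shape) < config.missing_cell_fraction
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, gene_of_row, scale_tag="unknown")


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a pre/post exercise cohort (see module docstring).

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical cohort.
    """
    config = replace(config or SyntheticConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pre + config.n_post
    samples = [f"S{i + 1:03d}" for i in range(n)]
    post_cols = np.arange(config.n_pre, n)

    model, layout = _truth_model(config)
    arm_sign = {"M1": -1.0, "M2": 1.0}
    offset = config.shift * arm_sign[config.shift_arm]

    rows, data, noise_of_gene = [], [], {}
    for cluster_id, group in layout.groupby("cluster_id", sort=False):
        latent = rng.integers(0, 2, size=n).astype(float)
        base = config.low_mean + latent * (config.high_mean - config.low_mean)
        arm = group["arm"].iloc[0]
        for gene in group["gene"]:
            noise = rng.normal(0.0, config.noise_sd, size=n)
            vals = base + noise
            if arm == config.shift_arm and offset != 0.0:
                vals = vals.copy()
                vals[post_cols] += offset
            rows.append(gene)
            data.append(vals)
            noise_of_gene[gene] = noise
    null_means = rng.uniform(config.low_mean, config.high_mean, size=config.n_null_genes)
    for i in range(config.n_null_genes):
        rows.append(f"NULL{i + 1:04d}")
        data.append(null_means[i] + rng.normal(0.0, config.noise_sd, size=n))

    values = pd.DataFrame(np.asarray(data), index=rows, columns=samples)
    gene_of_row = pd.Series(values.index, index=values.index)
    matrix = _inject_artifacts(values, gene_of_row, layout, config, rng, noise_of_gene)

    condition = ["pre"] * config.n_pre + ["post"] * config.n_post
    timepoint = "immediate" if config.shift_arm == "M1" else "long_term"
    annotation = SampleAnnotation(pd.DataFrame(
        {"condition": condition, "timepoint_class": timepoint},
        index=pd.Index(samples, name="sample_id")))
    return SyntheticCohort(matrix=matrix, annotation=annotation,
                           truth_model=model, truth_shift=config.shift,
                           config=config)


def generate_polarized_set(n_m1: int, n_m2: int,
                           config: SyntheticConfig | None = None,
                           **overrides) -> SyntheticCohort:
    """Generate polarized macrophage samples labeled M1/M2.

    M1-arm cluster genes are high in M1-labeled samples and low in
    M2-labeled samples, and vice versa — so any polarization signature
    should separate the two labels (`condition` column holds M1/M2; use
    ``positive_label="M2"`` when evaluating).
    """
    if n_m1 <= 0 or n_m2 <= 0:
        raise ValueError("n_m1 and n_m2 must both be positive")
    config = replace(config or SyntheticConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = n_m1 + n_m2
    samples = [f"P{i + 1:03d}" for i in range(n)]
    labels = np.array(["M1"] * n_m1 + ["M2"] * n_m2)

    model, layout = _truth_model(config)
    rows, data, noise_of_gene = [], [], {}
    for cluster_id, group in layout.groupby("cluster_id", sort=False):
        arm = group["arm"].iloc[0]
        latent = (labels == arm).astype(float)    # high when sample matches the arm
        base = config.low_mean + latent * (config.high_mean - config.low_mean)
        for gene in group["gene"]:
            noise = rng.normal(0.0, config.noise_sd, size=n)
            rows.append(gene)
            data.append(base + noise)
            noise_of_gene[gene] = noise
    for i in range(config.n_null_genes):
        mean = rng.uniform(config.low_mean, config.high_mean)
        rows.append(f"NULL{i + 1:04d}")
        data.append(mean + rng.normal(0.0, config.noise_sd, size=n))

    values = pd.DataFrame(np.asarray(data), index=rows, columns=samples)
    gene_of_row = pd.Series(values.index, index=values.index)
    matrix = _inject_artifacts(values, gene_of_row, layout, config, rng, noise_of_gene)
    annotation = SampleAnnotation(pd.DataFrame(
        {"condition": labels}, index=pd.Index(samples, name="sample_id")))
    return SyntheticCohort(matrix=matrix, annotation=annotation,
                           truth_model=model, truth_shift=0.0, config=config)


def generate_signature_screen_cohort(n_true: int = 30, n_null: int = 300,
                                     effect: float = 1.0, n_pre: int = 20,
                                     n_post: int = 20, noise_sd: float = 0.5,
                                     baseline: float = 6.0,
                                     seed: int = 0) -> SyntheticCohort:
    """Unimodal genes with a known discriminative subset, for AUC screening.

    Half of the ``n_true`` genes are shifted up by ``effect`` log2 units in
    post samples (expected AUC side > 0.5 → Group 1), half down (→ Group 2);
    the remainder are exchangeable between conditions.  At the defaults the
    asymptotic per-gene AUC is Φ(effect/(noise_sd·√2)) ≈ 0.92.  The truth
    model lists every gene (arm M2, weight +1, own cluster); the implanted
    direction is recorded in the model's entries under ``direction``
    (+1 up, −1 down, 0 null).
    """
    if n_true <= 0 or n_null < 0:
        raise ValueError("n_true must be positive and n_null nonnegative")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    samples = [f"S{i + 1:03d}" for i in range(n)]
    post_cols = np.arange(n_pre, n)
    n_up = n_true // 2 + n_true % 2
    directions = [1] * n_up + [-1] * (n_true - n_up) + [0] * n_null
    rows, data = [], []
    for i, direction in enumerate(directions):
        gene = (f"TRUE{i + 1:03d}" if direction else f"NULL{i - n_true + 1:04d}")
        vals = baseline + rng.normal(0.0, noise_sd, size=n)
        if direction:
            vals[post_cols] += direction * effect
        rows.append(gene)
        data.append(vals)
    values = pd.DataFrame(np.asarray(data), index=rows, columns=samples)
    matrix = ExpressionMatrix(values)
    annotation = SampleAnnotation(pd.DataFrame(
        {"condition": ["pre"] * n_pre + ["post"] * n_post},
        index=pd.Index(samples, name="sample_id")))
    entries = pd.DataFrame({"gene": rows, "cluster_id": rows, "arm": "M2",
                            "weight": 1.0, "direction": directions})
    model = PolarizationModel(entries, name="signature_screen_truth",
                              source="generate_signature_screen_cohort")
    return SyntheticCohort(matrix=matrix, annotation=annotation,
                           truth_model=model, truth_shift=float(effect),
                           config=SyntheticConfig(n_pre=n_pre, n_post=n_post,
                                                  noise_sd=noise_sd, seed=seed,
                                                  clusters=(("M2", n_true + max(n_null, 1), 1.0),)))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write matrix/annotation/model TSVs consumable by every other module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": outdir / "matrix.tsv",
             "annotation": outdir / "annotation.tsv",
             "model": outdir / "model.tsv"}
    write_matrix(cohort.matrix, paths["matrix"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_model(cohort.truth_model, paths["model"])
    return paths
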