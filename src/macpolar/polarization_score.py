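"""Composite macrophage polarization score.

A polarization model assigns each gene to a Boolean cluster, an arm (M1 or
M2) and a signed weight.  Per gene, expression is normalized by a modified
Z-score centered on the StepMiner threshold:

    z = (x − (SThr + 0.5)) / (3 · stdev)

then genes of a cluster are averaged (all probe instances of a gene count as
separate instances) and the sample score is the weighted linear combination
Σ_c w_c · avg_c over clusters with at least one present gene.  By the sign
convention, M1-arm weights are negative and M2-arm weights positive, so a
lower composite score means a more M1 (pro-inflammatory) sample.  Model genes
absent from a dataset are ignored; per-sample missing values are ignored
within the cluster average.

The composite score itself gets a StepMiner threshold and a ±0.5 noise
margin; samples within the margin are flagged intermediate (the flag is
informational and never excludes samples from evaluation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .stepminer import fit_rows, fit_step

log = logging.getLogger("macpolar")

ARMS = ("M1", "M2")
ARM_FILTERS = ("both", "M1_only", "M2_only")

#: floor for the per-gene standard deviation (guards degenerate variance)
STDEV_FLOOR = 1e-3


@dataclass
class PolarizationModel:
    """gene → (cluster_id, arm, weight) mapping defining the composite score.

    ``entries`` has columns gene, cluster_id, arm, weight; genes are unique;
    all genes of a cluster share one weight (the cluster weight w_c).
    """

    entries: pd.DataFrame
    name: str = "model"
    source: str = ""

    def __post_init__(self) -> None:
        required = {"gene", "cluster_id", "arm", "weight"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"model {self.name!r} lacks column(s) {sorted(missing)}")
        self.entries = self.entries.reset_index(drop=True)
        if self.entries["gene"].duplicated().any():
            dups = self.entries.loc[self.entries["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"model {self.name!r} has duplicate gene(s) {dups}")
        bad_arm = ~self.entries["arm"].isin(ARMS)
        if bad_arm.any():
            raise ValueError(f"model {self.name!r}: arm must be M1 or M2")
        w = self.entries["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w == 0):
            raise ValueError(f"model {self.name!r}: weights must be finite and nonzero")
        per_cluster = self.entries.groupby("cluster_id")["weight"].nunique()
        if (per_cluster > 1).any():
            bad = per_cluster.index[per_cluster > 1].tolist()
            raise ValueError(f"model {self.name!r}: inconsistent weights in cluster(s) {bad}")

    @property
    def genes(self) -> pd.Series:
        return self.entries["gene"]

    def __len__(self) -> int:
        return len(self.entries)

    def cluster_weights(self) -> pd.Series:
        return self.entries.groupby("cluster_id")["weight"].first()

    def filter_arm(self, arm_filter: str = "both") -> "PolarizationModel":
        arm_filter = _canonical_arm_filter(arm_filter)
        if arm_filter == "both":
            return self
        arm = "M1" if arm_filter == "M1_only" else "M2"
        entries = self.entries[self.entries["arm"] == arm].reset_index(drop=True)
        return PolarizationModel(entries, name=f"{self.name}[{arm}]", source=self.source)

    def drop_genes(self, genes: Iterable[str]) -> "PolarizationModel":
        genes = set(genes)
        entries = self.entries[~self.entries["gene"].isin(genes)].reset_index(drop=True)
        return PolarizationModel(entries, name=self.name, source=self.source)


def _canonical_arm_filter(arm_filter: str) -> str:
    key = arm_filter.lower().replace("_only", "")
    mapping = {"both": "both", "m1": "M1_only", "m2": "M2_only"}
    if key not in mapping:
        raise ValueError(f"arm_filter must be one of {ARM_FILTERS}, got {arm_filter!r}")
    return mapping[key]


def read_model(path: str | Path, name: str | None = None) -> PolarizationModel:
    """Read a model file (TSV: gene, cluster_id, arm, weight).

    A missing weight column defaults to −1 for M1-arm and +1 for M2-arm
    genes (lower score = more M1).
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster_id": str})
    if "weight" not in table.columns:
        table["weight"] = np.where(table["arm"] == "M1", -1.0, 1.0)
    return PolarizationModel(table, name=name or Path(path).stem, source=str(path))


def write_model(model: PolarizationModel, path: str | Path) -> None:
    model.entries[["gene", "cluster_id", "arm", "weight"]].to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene normalization
# ---------------------------------------------------------------------------


def gene_scale_stats(matrix: ExpressionMatrix, rows=None,
                     fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-row StepMiner threshold and (floored) sample standard deviation.

    ``fits`` may carry precomputed StepMiner results (from ``binarize``) to
    avoid refitting.  stdev uses ddof=1 over present values, floored at
    :data:`STDEV_FLOOR`.
    """
    ids = matrix.row_ids if rows is None else pd.Index(rows)
    if fits is None or not ids.isin(fits.index).all():
        fits = fit_rows(matrix, rows=ids)
    thr = fits.loc[ids, "threshold"]
    arr = matrix.values.loc[ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(arr, axis=1, ddof=1)
    sd = np.maximum(np.nan_to_num(sd, nan=0.0), STDEV_FLOOR)
    return pd.DataFrame({"threshold": thr.to_numpy(), "stdev": sd}, index=ids)


def normalize_gene(values, thr: float, stdev: float) -> np.ndarray:
    """Modified Z-score: (x − (SThr + 0.5)) / (3 · stdev); missing stays missing."""
    if stdev <= 0:
        raise ValueError("stdev must be positive (apply the floor first)")
    return (np.asarray(values, dtype=float) - (thr + 0.5)) / (3.0 * stdev)


def normalize_matrix(matrix: ExpressionMatrix, rows=None,
                     stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Row-wise modified Z-scores for (a subset of) matrix rows."""
    ids = matrix.row_ids if rows is None else pd.Index(rows)
    if stats is None:
        stats = gene_scale_stats(matrix, rows=ids)
    arr = matrix.values.loc[ids].to_numpy(dtype=float)
    thr = stats.loc[ids, "threshold"].to_numpy()[:, None]
    sd = stats.loc[ids, "stdev"].to_numpy()[:, None]
    return pd.DataFrame((arr - (thr + 0.5)) / (3.0 * sd),
                        index=ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# Composite score
# ---------------------------------------------------------------------------


def composite_score(matrix: ExpressionMatrix, model: PolarizationModel,
                    arm_filter: str = "both",
                    stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Composite polarization score per sample.

    Returns a DataFrame indexed by sample id with columns ``score`` and
    ``n_genes_used`` (distinct model genes with at least one present probe
    value for that sample).  Raises if no model gene is present in the
    matrix.
    """
    model = model.filter_arm(arm_filter)
    gene_set = set(model.genes)
    row_mask = matrix.gene_of_row.isin(gene_set).to_numpy()
    rows = matrix.row_ids[row_mask]
    if len(rows) == 0:
        raise ValueError(
            f"no gene of model {model.name!r} ({len(model)} genes) is present "
            "in the expression matrix")
    z = normalize_matrix(matrix, rows=rows, stats=stats)
    gene_of_row = matrix.gene_of_row.loc[rows]
    cluster_of_gene = model.entries.set_index("gene")["cluster_id"]
    cluster_of_row = gene_of_row.map(cluster_of_gene)

    # per-cluster mean of present normalized values (probe instances included)
    zmat = z.to_numpy()
    present = ~np.isnan(zmat)
    cluster_ids, cluster_codes = np.unique(cluster_of_row.to_numpy(), return_inverse=True)
    n_clusters, n_samples = len(cluster_ids), zmat.shape[1]
    sums = np.zeros((n_clusters, n_samples))
    counts = np.zeros((n_clusters, n_samples))
    np.add.at(sums, cluster_codes, np.nan_to_num(zmat, nan=0.0))
    np.add.at(counts, cluster_codes, present.astype(float))
    with np.errstate(invalid="ignore"):
        cluster_avg = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)

    weights = model.cluster_weights().reindex(cluster_ids).to_numpy(dtype=float)
    contrib = weights[:, None] * cluster_avg
    score = np.nansum(contrib, axis=0)
    # a sample with no present model value at all gets a missing score
    any_present = present.any(axis=0)
    score = np.where(any_present, score, np.nan)

    gene_codes = pd.factorize(gene_of_row.to_numpy())[0]
    n_genes = np.zeros((gene_codes.max() + 1, n_samples))
    np.add.at(n_genes, gene_codes, present.astype(float))
    n_genes_used = (n_genes > 0).sum(axis=0)

    return pd.DataFrame({"score": score, "n_genes_used": n_genes_used.astype(int)},
                        index=matrix.sample_ids)


def rank_samples(scores: pd.DataFrame, margin: float = 0.5) -> pd.DataFrame:
    """Order samples by composite score and flag the composite noise margin.

    Samples are sorted ascending (stable, so equal scores keep input order).
    The composite StepMiner threshold is fitted to the score distribution and
    samples with |score − threshold| ≤ margin (boundary inclusive) are
    flagged intermediate.
    """
    out = scores.copy()
    present = out["score"].dropna()
    try:
        thr = fit_step(present.to_numpy()).threshold
    except ValueError:
        thr = float("nan")
    out["intermediate_flag"] = (out["score"] - thr).abs() <= margin
    out.loc[out["score"].isna(), "intermediate_flag"] = False
    out["composite_threshold"] = thr
    return out.sort_values("score", kind="stable")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
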