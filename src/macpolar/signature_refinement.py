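"""Derivation of a muscle-resident macrophage polarization signature.

Starting from a full polarization model, each model gene present in a
derivation dataset is screened by the ROC-AUC of its (normalized) expression
between the pre and post exercise conditions.  Genes separating with
|AUC − 0.5| ≥ 0.2 — i.e. AUC ≥ 0.7 or ≤ 0.3, boundaries inclusive — are
selected; those with AUC above 0.5 form Group 1 and those below 0.5 form
Group 2, each gene keeping its arm and weight from the source model.  Since
the per-gene normalization is monotone, screening on normalized or raw
expression yields identical AUCs.

The refined 25-gene muscle-resident signature (3 M1 genes, 22 M2 genes)
ships as a packaged model file usable anywhere a polarization model is
accepted.  Tissue comparisons (spleen vs heart/skeletal muscle) use an
equal-weight (+1) score over a gene set, which is invariant to arm labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import GroupComparison, compare_groups
from .expression_io import ExpressionMatrix, SampleAnnotation
from .evaluation import roc_auc
from .polarization_score import (PolarizationModel, composite_score,
                                 normalize_matrix)

log = logging.getLogger("macpolar")

SELECT_HI = 0.7
SELECT_LO = 0.3


@dataclass
class GeneAUC:
    """Per-gene pre-vs-post discrimination (positive class = post/trained)."""

    gene: str
    arm: str
    auc: float
    selected: bool = False


@dataclass
class SignatureGroups:
    """Partition of selected genes by AUC side: Group 1 (> 0.5), Group 2 (< 0.5)."""

    group1: list[str]
    group2: list[str]
    table: pd.DataFrame   # gene, arm, auc, weight, group

    @property
    def selected(self) -> list[str]:
        return self.group1 + self.group2


def per_gene_auc(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                 model: PolarizationModel,
                 positive_label: str | None = None) -> list[GeneAUC]:
    """ROC-AUC of each present model gene's normalized expression, pre vs post.

    Genes absent from the matrix are omitted.  For multi-probe genes the
    per-sample mean of the gene's normalized probe rows is used (consistent
    with cluster averaging in the composite score).
    """
    annotation.validate_with_matrix(matrix)
    sub = matrix.subset_samples(annotation.sample_ids)
    neg_ids, pos_ids, _, _ = annotation.condition_split(positive_label)
    gene_set = set(model.genes)
    rows = sub.row_ids[sub.gene_of_row.isin(gene_set).to_numpy()]
    if len(rows) == 0:
        return []
    z = normalize_matrix(sub, rows=rows)
    z["__gene"] = sub.gene_of_row.loc[rows].to_numpy()
    per_gene = z.groupby("__gene").mean()
    arm_of_gene = model.entries.set_index("gene")["arm"]
    out: list[GeneAUC] = []
    for gene in model.genes:
        if gene not in per_gene.index:
            continue
        vals = per_gene.loc[gene]
        pre = vals.loc[neg_ids].dropna()
        post = vals.loc[pos_ids].dropna()
        if len(pre) == 0 or len(post) == 0:
            log.warning("per_gene_auc: gene %s has an empty condition group; omitted", gene)
            continue
        out.append(GeneAUC(gene=gene, arm=arm_of_gene[gene],
                           auc=roc_auc(pre.to_numpy(), post.to_numpy())))
    return out


def select_signature(gene_aucs: Sequence[GeneAUC], hi: float = SELECT_HI,
                     lo: float = SELECT_LO,
                     source_model: PolarizationModel | None = None
                     ) -> SignatureGroups:
    """Select genes with AUC ≥ hi or ≤ lo (inclusive) and split by AUC side.

    Group 1: AUC > 0.5; Group 2: AUC < 0.5.  Arms are retained per gene;
    weights are carried over from *source_model* when given, else ±1 by arm.
    """
    weight_of = (source_model.entries.set_index("gene")["weight"]
                 if source_model is not None else None)
    rows = []
    for ga in gene_aucs:
        ga.selected = bool(ga.auc >= hi or ga.auc <= lo)
        if not ga.selected:
            continue
        group = "group1" if ga.auc > 0.5 else "group2"
        weight = (float(weight_of[ga.gene]) if weight_of is not None
                  and ga.gene in weight_of.index
                  else (-1.0 if ga.arm == "M1" else 1.0))
        rows.append({"gene": ga.gene, "arm": ga.arm, "auc": ga.auc,
                     "weight": weight, "group": group})
    table = pd.DataFrame(rows, columns=["gene", "arm", "auc", "weight", "group"])
    group1 = table.loc[table["group"] == "group1", "gene"].tolist()
    group2 = table.loc[table["group"] == "group2", "gene"].tolist()
    if not group1 and not group2:
        log.warning("select_signature: no gene passed |AUC| selection (hi=%s, lo=%s)",
                    hi, lo)
    return SignatureGroups(group1=group1, group2=group2, table=table)


def signature_model(groups: SignatureGroups, group: str = "group2",
                    name: str | None = None) -> PolarizationModel:
    """Turn one signature group into a scoreable polarization model.

    Each gene becomes its own cluster with its carried-over weight.
    """
    if group not in ("group1", "group2"):
        raise ValueError("group must be 'group1' or 'group2'")
    sub = groups.table[groups.table["group"] == group]
    if sub.empty:
        raise ValueError(f"signature {group} is empty")
    entries = pd.DataFrame({"gene": sub["gene"], "cluster_id": sub["gene"],
                            "arm": sub["arm"], "weight": sub["weight"]})
    return PolarizationModel(entries, name=name or f"signature_{group}")


# ---------------------------------------------------------------------------
# Packaged 25-gene muscle-resident signature
# ---------------------------------------------------------------------------


def packaged_muscle_signature() -> PolarizationModel:
    """The refined 25-gene muscle-resident polarization signature.

    3 M1-arm genes (weight −1) and 22 M2-arm genes (weight +1); each gene is
    its own cluster.
    """
    ref = resources.files("macpolar.data").joinpath("muscle_signature_25.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster_id": str})
    return PolarizationModel(table, name="muscle_resident_macrophage_25",
                             source="packaged")


# ---------------------------------------------------------------------------
# Tissue comparison
# ---------------------------------------------------------------------------


def tissue_compare(matrix: ExpressionMatrix, tissues: Mapping[str, str] | pd.Series,
                   gene_set: Iterable[str], positive: str = "spleen",
                   label: str = "tissue", alpha: float = 0.05) -> GroupComparison:
    """Equal-weight (+1) composite comparison between two tissue groups.

    *tissues* maps sample id → tissue label with exactly two levels; the
    *positive* level (default spleen, the macrophage-rich tissue) is the
    ROC positive class.  All genes get weight +1 regardless of arm, so the
    comparison reads out shared signature expression, not polarization
    direction.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("tissue_compare requires a non-empty gene set")
    tissues = pd.Series(dict(tissues)) if not isinstance(tissues, pd.Series) else tissues
    levels = sorted(tissues.dropna().unique().tolist())
    if positive not in levels:
        raise ValueError(f"tissue level {positive!r} missing (found {levels})")
    if len(levels) != 2:
        raise ValueError(f"tissue comparison requires exactly two levels, got {levels}")
    other = next(lv for lv in levels if lv != positive)
    entries = pd.DataFrame({"gene": genes, "cluster_id": genes,
                            "arm": "M2", "weight": 1.0})
    model = PolarizationModel(entries, name=f"equal_weight[{label}]")
    sub = matrix.subset_samples(tissues.index)
    scores = composite_score(sub, model)["score"]
    neg = scores.loc[tissues.index[tissues == other]].dropna()
    pos = scores.loc[tissues.index[tissues == positive]].dropna()
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError(f"{label}: need >= 2 scored samples per tissue")
    return compare_groups(neg.to_numpy(), pos.to_numpy(), label=label, alpha=alpha,
                          pre_label=other, post_label=positive)
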