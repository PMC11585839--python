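"""Pre/post separation of composite scores: ROC-AUC, Welch's t, reports.

The ROC-AUC uses the rank (Mann–Whitney) formulation with midrank tie
correction and the post-exercise/trained group as the positive class, so an
AUC below 0.5 means post samples score *lower* (the M1 direction) and above
0.5 the M2 direction.  Group means are compared with Welch's two-sample
t-test (unpaired, unequal variance and sample size), two-sided.  No
multiple-testing correction is applied across datasets by default; an
optional Benjamini–Hochberg column is available in report tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression_io import ExpressionMatrix, SampleAnnotation
from .polarization_score import PolarizationModel, composite_score

log = logging.getLogger("macpolar")

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Per-dataset (or per-subgroup) two-group comparison of composite scores."""

    label: str
    n_pre: int
    n_post: int
    auc: float
    t_stat: float
    p_value: float
    neg_log10_p: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    pre_label: str = "pre"
    post_label: str = "post"

    def as_row(self) -> dict:
        return {"label": self.label, "n_pre": self.n_pre, "n_post": self.n_post,
                "auc": self.auc, "t": self.t_stat, "p": self.p_value,
                "neg_log10_p": self.neg_log10_p, "significant": self.significant}


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def roc_auc(pre_scores: Sequence[float], post_scores: Sequence[float]) -> float:
    """Probability that a random post sample scores above a random pre sample.

    Mann–Whitney formulation with midrank ties:
    AUC = [#(post > pre) + ½·#(ties)] / (n_pre · n_post).
    """
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("roc_auc requires both groups non-empty")
    ranks = sps.rankdata(np.concatenate([post, pre]))
    u_post = float(ranks[:post.size].sum()) - post.size * (post.size + 1) / 2.0
    return u_post / (pre.size * post.size)


def welch_t(pre_scores: Sequence[float], post_scores: Sequence[float]
            ) -> tuple[float, float]:
    """Welch's two-sample t statistic and two-sided p (unequal variance/size).

    Degenerate zero-variance groups: identical means give (0, 1); distinct
    means give (±inf, 0).
    """
    pre = np.asarray(pre_scores, dtype=float)
    post = np.asarray(post_scores, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("welch_t requires n >= 2 in each group")
    if pre.var(ddof=1) == 0.0 and post.var(ddof=1) == 0.0:
        diff = post.mean() - pre.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    res = sps.ttest_ind(post, pre, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def neg_log10(p: float) -> float:
    return math.inf if p == 0.0 else -math.log10(p)


# ---------------------------------------------------------------------------
# Dataset evaluation
# ---------------------------------------------------------------------------


def compare_groups(pre_scores: Sequence[float], post_scores: Sequence[float],
                   label: str = "dataset", alpha: float = DEFAULT_ALPHA,
                   pre_label: str = "pre", post_label: str = "post"
                   ) -> GroupComparison:
    """ROC-AUC + Welch's t on two score groups (positive class = post)."""
    auc = roc_auc(pre_scores, post_scores)
    t, p = welch_t(pre_scores, post_scores)
    return GroupComparison(label=label, n_pre=len(pre_scores), n_post=len(post_scores),
                           auc=auc, t_stat=t, p_value=p, neg_log10_p=neg_log10(p),
                           significant=bool(p < alpha), alpha=alpha,
                           pre_label=pre_label, post_label=post_label)


def evaluate_dataset(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                     model: PolarizationModel, arm_filter: str = "both",
                     alpha: float = DEFAULT_ALPHA, label: str = "dataset",
                     positive_label: str | None = None,
                     stats: pd.DataFrame | None = None) -> GroupComparison:
    """Composite-score pre/post comparison for one dataset.

    Scores are computed over the annotated samples only; both condition
    groups need at least two samples.
    """
    annotation.validate_with_matrix(matrix)
    sub = matrix.subset_samples(annotation.sample_ids)
    scores = composite_score(sub, model, arm_filter=arm_filter, stats=stats)["score"]
    neg_ids, pos_ids, neg_label, pos_label = annotation.condition_split(positive_label)
    pre = scores.loc[neg_ids].dropna()
    post = scores.loc[pos_ids].dropna()
    if len(pre) < 2 or len(post) < 2:
        raise ValueError(
            f"{label}: need >= 2 scored samples per group "
            f"({neg_label}: {len(pre)}, {pos_label}: {len(post)})")
    return compare_groups(pre.to_numpy(), post.to_numpy(), label=label,
                          alpha=alpha, pre_label=neg_label, post_label=pos_label)


def subgroup_compare(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                     field_name: str, model: PolarizationModel,
                     arm_filter: str = "both", alpha: float = DEFAULT_ALPHA,
                     label: str = "dataset",
                     positive_label: str | None = None) -> list[GroupComparison]:
    """Evaluate each level of a subgroup field separately.

    Levels where either condition group has fewer than two samples are
    skipped with a warning.
    """
    if field_name not in annotation.table.columns:
        raise ValueError(f"unknown subgroup field {field_name!r}; available: "
                         f"{list(annotation.table.columns)}")
    comparisons: list[GroupComparison] = []
    for level in sorted(annotation.table[field_name].dropna().unique()):
        ids = annotation.table.index[annotation.table[field_name] == level]
        sub_ann = annotation.subset(ids)
        counts = sub_ann.table["condition"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            log.warning("%s: subgroup %s=%s skipped (insufficient samples per "
                        "condition: %s)", label, field_name, level, counts.to_dict())
            continue
        comparisons.append(evaluate_dataset(
            matrix.subset_samples(ids), sub_ann, model, arm_filter=arm_filter,
            alpha=alpha, label=f"{label}:{field_name}={level}",
            positive_label=positive_label))
    return comparisons


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def report_table(comparisons: Iterable[GroupComparison],
                 bh_adjust: bool = False) -> pd.DataFrame:
    """Tabulate comparisons; optionally add a Benjamini–Hochberg column."""
    table = pd.DataFrame([c.as_row() for c in comparisons])
    if bh_adjust and len(table):
        from statsmodels.stats.multitest import multipletests
        table["p_bh"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def dot_plot(table: pd.DataFrame, path: str | Path,
             title: str = "pre/post separation") -> None:
    """AUC-vs-dataset dot plot, dot size proportional to −log10 p."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(table))))
    sizes = np.clip(np.nan_to_num(table["neg_log10_p"].to_numpy(), posinf=10.0), 0, 10)
    ax.scatter(table["auc"], range(len(table)), s=20 + 30 * sizes,
               c=np.where(table["significant"], "tab:red", "tab:gray"))
    ax.axvline(0.5, color="k", lw=0.8, ls="--")
    ax.set_yticks(range(len(table)), table["label"])
    ax.set_xlabel("ROC-AUC (positive class = post/trained)")
    ax.set_xlim(0, 1)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
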