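"""Reproducible dataset runs and cross-dataset meta summaries.

``run_dataset`` executes binarize → (optional) Boolean relations/network →
composite score → pre/post evaluation (plus per-subgroup comparisons) for one
dataset and writes every stage table plus a manifest recording all parameters
and output hashes; rerunning the same configuration reproduces every file
byte for byte.  ``run_meta`` aggregates many dataset runs into the
per-dataset report and the significant/total summary counts, split by
timepoint class and any subgroup fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .boolean_implication import (all_pairs_relations, build_network,
                                  cluster_equivalent, write_network,
                                  write_relations)
from .evaluation import (GroupComparison, evaluate_dataset, report_table,
                         subgroup_compare, write_report)
from .expression_io import read_annotation, read_matrix
from .polarization_score import (composite_score, gene_scale_stats, read_model,
                                 rank_samples, write_scores)
from .stepminer import binarize, write_fits, write_tristate

log = logging.getLogger("macpolar")


@dataclass
class RunConfig:
    """Everything that affects any number in a dataset run's outputs."""

    matrix: str
    annotation: str
    model: str
    out: str
    label: str = "dataset"
    matrix_format: str = "tsv"
    margin: float = 0.5
    sthr: float = 3.0
    pthr: float = 0.1
    alpha: float = 0.05
    hi: float = 0.7
    lo: float = 0.3
    arm_filter: str = "both"
    min_fstat: float | None = None
    compute_relations: bool = False
    subgroup_fields: tuple[str, ...] = ()
    positive_label: str | None = None
    timepoint_class: str | None = None
    seed: int = 0

    def validate_paths(self) -> None:
        for role in ("matrix", "annotation", "model"):
            path = Path(getattr(self, role))
            if not path.exists():
                raise FileNotFoundError(f"config error: {role} file not found: {path}")


_BOOL_KEYS = {"compute_relations"}
_FLOAT_KEYS = {"margin", "sthr", "pthr", "alpha", "hi", "lo", "min_fstat"}
_INT_KEYS = {"seed"}


def read_run_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a plain ``key = value`` config file; keyword overrides win.

    ``subgroup_fields`` is a comma-separated list; flag names mirror the CLI.
    """
    raw: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _BOOL_KEYS:
            raw[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in _FLOAT_KEYS:
            raw[key] = float(value)
        elif key in _INT_KEYS:
            raw[key] = int(value)
        elif key == "subgroup_fields":
            raw[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        else:
            raw[key] = value
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)   # type: ignore[arg-type]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_dataset(config: RunConfig) -> dict:
    """Run all stages for one dataset; returns paths, comparison and manifest."""
    config.validate_paths()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        matrix = read_matrix(config.matrix, format=config.matrix_format)
        annotation = read_annotation(config.annotation)
        model = read_model(config.model)
        annotation.validate_with_matrix(matrix)

        stage = "binarize"
        tri = binarize(matrix, margin=config.margin, min_fstat=config.min_fstat)
        write_fits(tri.fits, outdir / "stepminer_fits.tsv")
        write_tristate(tri, outdir / "tristate.tsv")

        if config.compute_relations:
            stage = "boolean relations"
            relations = all_pairs_relations(tri, sthr=config.sthr, pthr=config.pthr,
                                            with_stats=True)
            write_relations(relations, outdir / "relations.tsv")
            network = build_network(cluster_equivalent(relations), relations)
            write_network(network, outdir / "network_edges.tsv",
                          outdir / "network_clusters.tsv")

        stage = "composite score"
        stats = gene_scale_stats(matrix, fits=tri.fits)
        scores = composite_score(matrix, model, arm_filter=config.arm_filter,
                                 stats=stats)
        ranked = rank_samples(scores, margin=config.margin)
        write_scores(ranked, outdir / "scores.tsv")

        stage = "evaluate"
        comparison = evaluate_dataset(matrix, annotation, model,
                                      arm_filter=config.arm_filter,
                                      alpha=config.alpha, label=config.label,
                                      positive_label=config.positive_label,
                                      stats=stats)
        comparisons = [comparison]
        for field_name in config.subgroup_fields:
            comparisons.extend(subgroup_compare(
                matrix, annotation, field_name, model,
                arm_filter=config.arm_filter, alpha=config.alpha,
                label=config.label, positive_label=config.positive_label))
        write_report(report_table(comparisons), outdir / "report.tsv")
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed for {config.label}: {err}") from err

    params = dataclasses.asdict(config)
    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "package_version": __version__,
        "parameters": params,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return {"outdir": outdir, "comparison": comparison,
            "comparisons": comparisons, "manifest": manifest}


def run_meta(configs: list[RunConfig], alpha: float = 0.05) -> dict:
    """Run many datasets and summarize significant/total counts.

    Returns the per-dataset table (id, timepoint_class, auc, p, significant)
    and summary counts overall and split by timepoint class.
    """
    if not configs:
        raise ValueError("run_meta requires at least one dataset config")
    rows = []
    for config in configs:
        result = run_dataset(config)
        comp: GroupComparison = result["comparison"]
        rows.append({"dataset": config.label,
                     "timepoint_class": config.timepoint_class or "unspecified",
                     "n_pre": comp.n_pre, "n_post": comp.n_post,
                     "auc": comp.auc, "p": comp.p_value,
                     "neg_log10_p": comp.neg_log10_p,
                     "significant": bool(comp.p_value < alpha)})
    per_dataset = pd.DataFrame(rows)
    summaries = [{"group": "all", "n_significant": int(per_dataset["significant"].sum()),
                  "n_total": len(per_dataset)}]
    for klass, sub in per_dataset.groupby("timepoint_class"):
        summaries.append({"group": f"timepoint_class={klass}",
                          "n_significant": int(sub["significant"].sum()),
                          "n_total": len(sub)})
    summary = pd.DataFrame(summaries)
    return {"per_dataset": per_dataset, "summary": summary}


def write_meta(meta: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta["per_dataset"].to_csv(outdir / "meta_report.tsv", sep="\t", index=False)
    meta["summary"].to_csv(outdir / "meta_summary.tsv", sep="\t", index=False)
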