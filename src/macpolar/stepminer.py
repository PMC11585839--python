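"""StepMiner: adaptive one-step regression for expression binarization.

For each gene the expression values are sorted ascending and a rising step
function is fitted by exhaustively evaluating every step position and keeping
the one that minimizes the sum of squared errors.  The midpoint of the fitted
step is the StepMiner threshold; a noise margin (default ±0.5 log2, i.e. a
2-fold band) around the threshold yields tri-state low / intermediate / high
calls, with intermediate values excluded from downstream Boolean analysis.

The regression statistic is

    F = [Σ(X̂ᵢ − X̄)² / (m − 1)] / [Σ(Xᵢ − X̂ᵢ)² / (n − m)]

with m = 3 degrees of freedom for the one-step fit (two segment means plus the
step position).  A perfect step (zero residual) returns +inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

log = logging.getLogger("macpolar")

#: tri-state call codes used in matrices and TSV output
LOW, INTERMEDIATE, HIGH = 0.0, 1.0, 2.0

#: degrees of freedom of the one-step adaptive regression
STEP_DOF = 3

_SSE_EPS = 1e-10


@dataclass
class StepFit:
    """Result of a one-step fit to one gene's (sorted) expression values."""

    threshold: float
    low_mean: float
    high_mean: float
    step_index: int          # number of samples in the low segment
    sse: float
    fstat: float
    n: int
    m: int = STEP_DOF
    degenerate: bool = False


def _fit_sorted(xs: np.ndarray, min_segment: int = 1) -> tuple[float, float, int, float]:
    """Best step on sorted values: (low_mean, high_mean, step_index, sse).

    Exhaustive search over all step positions k (low segment size), ties in
    SSE broken by the smallest k (first argmin).
    """
    n = xs.size
    prefix = np.cumsum(xs)
    total, sq = prefix[-1], float(np.dot(xs, xs))
    ks = np.arange(min_segment, n - min_segment + 1)
    if ks.size == 0:
        raise ValueError(f"min_segment={min_segment} leaves no valid step position for n={n}")
    pk = prefix[ks - 1]
    low_means = pk / ks
    high_means = (total - pk) / (n - ks)
    sse = sq - ks * low_means**2 - (n - ks) * high_means**2
    best = int(np.argmin(sse))
    return (float(low_means[best]), float(high_means[best]), int(ks[best]),
            float(max(sse[best], 0.0)))


def fit_step(values, min_segment: int = 1) -> StepFit:
    """Fit a one-step function to the present values of one gene.

    Values are sorted ascending internally; missing (NaN) entries are dropped.
    Raises ``ValueError`` with fewer than 2 present values.  A constant vector
    yields a degenerate fit (threshold = the constant, SSE 0, F 0).
    """
    xs = np.asarray(values, dtype=float)
    xs = np.sort(xs[~np.isnan(xs)], kind="stable")
    n = xs.size
    if n < 2:
        raise ValueError(f"fit_step requires >= 2 present values, got {n}")
    if xs[0] == xs[-1]:
        c = float(xs[0])
        return StepFit(threshold=c, low_mean=c, high_mean=c, step_index=n,
                       sse=0.0, fstat=0.0, n=n, degenerate=True)
    low, high, k, sse = _fit_sorted(xs, min_segment)
    fit = StepFit(threshold=(low + high) / 2.0, low_mean=low, high_mean=high,
                  step_index=k, sse=sse, fstat=np.nan, n=n)
    fit.fstat = fstat(xs, fit) if n > STEP_DOF else np.nan
    return fit


def fstat(values, fit: StepFit) -> float:
    """Regression statistic of a step fit (see module docstring).

    ``values`` must be the data the fit was produced from.  Requires
    n > m; zero residual SSE returns +inf, a degenerate (constant) fit 0.
    """
    xs = np.asarray(values, dtype=float)
    xs = xs[~np.isnan(xs)]
    n = xs.size
    if n <= fit.m:
        raise ValueError(f"fstat requires n > m ({fit.m}), got n={n}")
    if fit.degenerate:
        return 0.0
    total_ss = float(np.sum((xs - xs.mean()) ** 2))
    explained = max(total_ss - fit.sse, 0.0)
    if fit.sse <= _SSE_EPS:
        return float("inf")
    return (explained / (fit.m - 1)) / (fit.sse / (n - fit.m))


# ---------------------------------------------------------------------------
# Matrix binarization
# ---------------------------------------------------------------------------


@dataclass
class TriStateMatrix:
    """Per-(row, sample) calls in {low, intermediate, high, missing}.

    ``calls`` uses float codes 0/1/2 with NaN for missing.  ``fits`` is a
    per-row table (threshold, low_mean, high_mean, step_index, sse, fstat, n,
    degenerate).  ``excluded`` lists rows without usable Boolean information
    (degenerate, fit failures, or below the optional F-statistic gate); they
    are skipped during Boolean relation discovery.
    """

    calls: pd.DataFrame
    margin: float
    fits: pd.DataFrame
    excluded: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def included(self) -> pd.Index:
        return self.calls.index.difference(self.excluded, sort=False)


_FIT_COLUMNS = ["threshold", "low_mean", "high_mean", "step_index", "sse",
                "fstat", "n", "degenerate"]


def fit_rows(matrix: ExpressionMatrix, rows=None, min_segment: int = 1) -> pd.DataFrame:
    """Per-row :func:`fit_step` over (a subset of) the matrix rows.

    Rows with < 2 present values get all-NaN entries and are counted in a
    single warning.  Returns a DataFrame with :data:`_FIT_COLUMNS`.
    """
    ids = matrix.row_ids if rows is None else pd.Index(rows)
    arr = matrix.values.loc[ids].to_numpy(dtype=float)
    out = np.full((len(ids), len(_FIT_COLUMNS)), np.nan)
    n_failed = 0
    for i in range(arr.shape[0]):
        try:
            f = fit_step(arr[i], min_segment=min_segment)
        except ValueError:
            n_failed += 1
            continue
        out[i] = (f.threshold, f.low_mean, f.high_mean, f.step_index, f.sse,
                  f.fstat, f.n, float(f.degenerate))
    if n_failed:
        log.warning("fit_rows: skipped %d row(s) with < 2 present values", n_failed)
    fits = pd.DataFrame(out, index=ids, columns=_FIT_COLUMNS)
    fits["degenerate"] = fits["degenerate"].fillna(0.0).astype(bool)
    return fits


def binarize(matrix: ExpressionMatrix, margin: float = 0.5,
             min_segment: int = 1, min_fstat: float | None = None) -> TriStateMatrix:
    """StepMiner-binarize every row of an expression matrix.

    Calls: low if value < threshold − margin, high if value > threshold +
    margin, intermediate otherwise; missing stays missing.  Degenerate
    (constant) rows are called intermediate throughout and excluded from
    Boolean relation discovery, as are rows failing the optional
    ``min_fstat`` gate (default: no gate).
    """
    fits = fit_rows(matrix, min_segment=min_segment)
    arr = matrix.values.to_numpy(dtype=float)
    thr = fits["threshold"].to_numpy()[:, None]
    calls = np.full(arr.shape, INTERMEDIATE)
    calls[arr < thr - margin] = LOW
    calls[arr > thr + margin] = HIGH
    calls[np.isnan(arr)] = np.nan
    degenerate = fits["degenerate"].to_numpy()
    calls[degenerate & ~np.isnan(fits["threshold"]).to_numpy()] = INTERMEDIATE
    # restore missing cells on degenerate rows
    calls[np.isnan(arr)] = np.nan
    failed = np.isnan(fits["threshold"].to_numpy())
    calls[failed] = np.nan
    excluded = degenerate | failed
    if min_fstat is not None:
        f = fits["fstat"].to_numpy()
        excluded = excluded | ~(f >= min_fstat)   # NaN F fails the gate
    return TriStateMatrix(
        calls=pd.DataFrame(calls, index=matrix.row_ids, columns=matrix.sample_ids),
        margin=margin,
        fits=fits,
        excluded=matrix.row_ids[excluded])


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------


def write_fits(fits: pd.DataFrame, path: str | Path) -> None:
    fits.to_csv(path, sep="\t", index_label="row_id")


def write_tristate(tri: TriStateMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tri-state coding: 0=low, 1=intermediate, 2=high, NA=missing; "
                 f"margin={tri.margin}\n")
        tri.calls.to_csv(fh, sep="\t", na_rep="NA", index_label="row_id")
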