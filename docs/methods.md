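# Methods

## Scope and data model

`macpolar` scores macrophage polarization in bulk (and pre-summarized
single-cell) expression data and quantifies pre/post-exercise separation.
The in-memory container is a log2-scale gene-by-sample matrix in which rows
are probes or genes; several probe rows may map to one gene symbol and are
never collapsed — every probe instance participates in downstream averages.
Missing measurements are a dedicated missing marker (NaN in memory, blank
cells in TSV), never 0, because 0 is a legitimate expression value on the
log2(CPM+1) scale. RNA-seq counts are normalized to log2(CPM+1) (or
log2(RPKM+1) given gene lengths in kb); Affymetrix data are assumed
RMA-normalized upstream. Whether a downloaded matrix is already
log-transformed is not always recorded in public repositories, so a simple
overridable heuristic is provided: values above 30 are taken to indicate a
linear scale and `ensure_log2` applies log2(x+1); `force=True/False`
overrides the heuristic in either direction.

## StepMiner

Per gene, values are sorted ascending (stable sort; equal values keep input
order) and a rising one-step function is fitted by evaluating every step
position and keeping the SSE minimum; exact SSE ties are broken toward the
smallest low-segment size, making the fit deterministic. The threshold is
the midpoint of the fitted step, `(low_mean + high_mean)/2`. The
regression statistic is

    F = [Σ(X̂ᵢ − X̄)² / (m − 1)] / [Σ(Xᵢ − X̂ᵢ)² / (n − m)]

with m = 3 degrees of freedom (two segment means plus the step position).
Zero residual returns +inf; a constant gene is *degenerate*: threshold
equals the constant, all calls intermediate, F = 0, and the row is excluded
from Boolean relation discovery (no dynamic range means no implication
evidence). Tri-state calls use a ±0.5 log2 noise margin around the
threshold (a 2-fold band): low below, high above, intermediate inside;
missing stays missing. An optional F-statistic gate (`min_fstat`, default
off) can additionally exclude weakly-stepped rows from relation discovery,
since no published prefiltering rule is available.

## Boolean implication

For a gene pair, samples with both calls in {low, high} are cross-tabulated
into quadrants a00 (A low, B low), a01 (A low, B high), a10, a11.
Expected occupancy under independence is `n̂ = (nA/total)·(nB/total)·total`
using each quadrant's own marginals. Sparsity uses the BooleanNet
statistics `S = (n̂ − a)/√n̂` (S = 0 when n̂ = 0) and the error rate
`p = ½(a/nA + a/nB)` with zero-marginal terms set to 0. A quadrant is
sparse when `S > sThr` and `p < pThr`; defaults sThr = 3.0 and pThr = 0.1
follow the method family's convention and are configuration-exposed, so all
reported relations are threshold-annotated. Symmetric relations are
checked first (equivalent: a01 and a10 sparse; opposite: a00 and a11
sparse); an asymmetric implication requires *exactly one* sparse quadrant
(a00 → A low ⇒ B high, a01 → A low ⇒ B low, a10 → A high ⇒ B high, a11 →
A high ⇒ B low); anything else is no relation. Swapping the genes maps
types as expected (low_low ↔ high_high; the others are self-symmetric),
which the all-pairs routine exploits to compute each unordered pair once.
Relations are computed per dataset, not pooled across datasets.

Equivalence clusters are connected components over equivalent edges with
singletons pruned. Cluster-level edges are induced by majority vote: an
edge of a type exists when more than half of the inter-cluster gene pairs
carry that type, with the support fraction recorded (no published rule
specifies cluster-edge induction, so the simplest defensible one is used).

## Composite polarization score

A polarization model maps genes to (cluster, arm, weight), all genes of a
cluster sharing one weight. Genes are normalized with a modified Z-score
centered on the StepMiner threshold, `z = (x − (t + 0.5))/(3·sd)`, where
sd is the per-gene *sample* standard deviation (ddof = 1) over all dataset
samples, floored at 1e-3 to keep degenerate-variance genes finite. Cluster
averages (over all present probe instances) are combined linearly,
`score = Σ_c w_c · avg_c`, over clusters with at least one present value.
M1-arm weights are negative and M2-arm weights positive, so lower scores
mean more M1. Model genes missing from a dataset are ignored — deleting a
gene's data row and deleting the gene from the model give identical scores,
a property tested directly. Samples are ranked by score; the score
distribution itself is StepMiner-thresholded and samples within ±0.5 of
that composite threshold (boundary inclusive) are flagged intermediate.
The flag is informational only and never excludes samples from evaluation.
An `arm_filter` restricts scoring to one arm (used for cohorts where only
the M1 axis is interpretable); for disjoint arms the two restricted scores
sum to the full score.

## Evaluation

Separation is quantified by ROC-AUC in the rank (Mann–Whitney)
formulation with midrank tie handling, positive class = post/trained, so
AUC < 0.5 means post samples score lower (M1 direction). Group means are
compared with Welch's two-sample t-test (scipy's `ttest_ind` with
`equal_var=False`), two-sided, unpaired throughout — including
within-subject designs, since pairing information is rarely available in
the public annotations. Significance uses alpha = 0.05. Zero-variance
degenerate groups return (0, 1) for equal means and (±inf, 0) otherwise.
Per-dataset significance is reported without multiple-testing correction
(the meta summary counts significant datasets); an optional
Benjamini–Hochberg column is available in report tables. Subgroup
comparisons (gender, intensity, age group, tissue, …) rerun the same
evaluation per level, skipping levels with fewer than two samples in either
condition.

## Signature refinement

Model genes present in a derivation dataset are screened by per-gene AUC of
their normalized expression (normalization is monotone per gene, so the AUC
is identical on raw values — a tested identity; multi-probe genes use the
per-sample mean of their normalized probes, matching cluster averaging).
Genes with AUC ≥ 0.7 or ≤ 0.3 (inclusive — the published selection is
|AUC − 0.5| ≥ 0.2 with the boundary side unspecified) are selected; AUC >
0.5 → Group 1, < 0.5 → Group 2, arms and weights carried from the source
model. The derivation dataset is a configuration input rather than a
hard-coded accession. Tissue comparisons score a gene set with every
weight +1 (arm labels irrelevant by construction) and compare the
macrophage-rich tissue (spleen, the positive class) against heart/skeletal
muscle. The packaged 25-gene muscle-resident signature uses one cluster
per gene and ±1 weights, the neutral choice given that the original
cluster weights are not published.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure the method assumes:
each Boolean cluster draws an independent Bernoulli(0.5) latent state per
sample (low or high mode shared by the cluster's genes) plus Gaussian
noise, which guarantees per-gene bimodality and within-cluster equivalence;
null genes are unimodal noise. The exercise effect is an additive log2
shift applied to one arm's genes in post samples only. The `shift`
parameter is read on the composite-score scale — negative = M1 direction
(immediate response), positive = M2 direction (long-term training) — and
the expression-level offset is `shift × sign(arm weight)`.

Reference conditions (the defaults): 40 + 40 samples, matching a typical
per-condition size of public exercise datasets; a truth model mirroring the
published 338-gene model's shape (12 M1 clusters + 72 M2 clusters of 4
genes → 48 M1 / 288 M2 genes); per-arm-normalized cluster weights (−1/12,
+1/72) so both arms contribute equally to the composite; low/high modes at
4 and 7 log2 units; noise SD 0.5; 100 null genes. An a priori power
analysis fixed these: with them, the null AUC standard deviation at 40+40
is ≈ 0.065 (so the AUC stays within (0.35, 0.65) for ≈ 98% of null
cohorts) and a |shift| = 1 cohort at 20+20 has true AUC ≈ 0.93, detectable
on the correct side of the 0.3/0.7 bands with large margin. Missing cells,
entirely-dropped model genes and duplicated probe rows (same latent signal,
fresh measurement noise) are injected at configurable rates, default 0.

`generate_polarized_set` produces M1/M2-labeled samples with arm-consistent
expression; this — not the exercise cohort — is the regime where cross-arm
*opposite* relations exist, because in exercise cohorts the cluster states
are independent by design. `generate_signature_screen_cohort` produces
unimodal genes with a ±1 log2 post shift at noise SD 0.5 (asymptotic
per-gene AUC Φ(1/(0.5·√2)) ≈ 0.92), half up and half down, among nulls,
for two-sided screening experiments.

What passing tests on these cohorts do *not* show: robustness to RNA-seq
count noise (no negative-binomial library simulation), batch effects,
platform differences between microarray and sequencing, continuous (rather
than two-state) polarization gradients, or cell-type composition changes
confounding bulk signals. Results on synthetic cohorts demonstrate the
pipeline's correctness and calibration, not the biological effect sizes of
real exercise studies.

## Numerical choices and degenerate inputs

- Step-fit SSE is computed from prefix sums and clipped at 0; oracle
  comparisons use 1e-8 absolute tolerance.
- Residual SSE ≤ 1e-10 is treated as a perfect step (F = +inf).
- Gene standard deviations are floored at 1e-3 before division.
- Constant genes: degenerate fits, intermediate calls, excluded from
  relations, still scoreable (z is finite via the floor).
- Rows with fewer than two present values are skipped with a logged
  warning and carry missing calls.
- p-values of exactly 0 map to −log10 p = +inf in reports.
- All generators use a single seeded `numpy` Generator; identical
  configurations produce byte-identical cohorts and pipeline outputs
  (manifests record parameters and output hashes, no timestamps).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
2000 null cohorts for calibration, 100 seeds per arm for shift recovery,
50 seeds for the signature screen, and compact 6-cluster layouts where the
full-size model adds nothing. These sizes make the checks statistically
stable while keeping a full run on one CPU in the low minutes.
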