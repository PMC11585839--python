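# macpolar

Boolean-implication macrophage polarization scoring for pre/post-exercise
transcriptomics.

Exercise shifts the balance between pro-inflammatory (M1) and reparative
(M2) macrophages: an M1 surge within hours of a bout, and a sustained M2
tilt after weeks of training. Bulk muscle or blood expression profiles do
not measure macrophages directly, so the shift is read out with a composite
*macrophage polarization score* built on Boolean implication networks.
`macpolar` implements that pipeline as a tested, reusable library and CLI
for anyone who wants to score their own pre/post or sedentary/trained
expression datasets — or to study the method itself on synthetic cohorts
with known ground truth.

## Method

1. **StepMiner binarization.** Per gene, expression values are sorted and a
   one-step function is fitted by exhaustive search over step positions,
   minimizing the SSE. The mid-step is the threshold *t*; values within
   ±0.5 log2 of *t* (a 2-fold band) are *intermediate*. The step quality is
   `F = [Σ(X̂ᵢ−X̄)²/(m−1)] / [Σ(Xᵢ−X̂ᵢ)²/(n−m)]` with m = 3.
2. **Boolean implication.** For a gene pair, samples with both calls in
   {low, high} fill quadrants a00, a01, a10, a11. A quadrant is sparse when
   `S = (n̂−a)/√n̂ > 3` and `p = ½(a/nA + a/nB) < 0.1`, where n̂ is the
   occupancy expected under independence. Two sparse diagonal quadrants
   give *equivalent* or *opposite*; exactly one gives one of the four
   asymmetric implications (e.g. sparse a00 → "A low ⇒ B high").
   Equivalence components (singletons pruned) are the network's nodes.
3. **Composite score.** Each model gene is normalized by a modified
   Z-score, `z = (x − (t + 0.5)) / (3·sd)`, genes are averaged within their
   cluster (every probe instance counts) and the sample score is
   `Σ_c w_c · avg_c`. M1-arm weights are negative, so **lower score = more
   M1**. Model genes absent from a dataset are ignored; missing values are
   ignored inside cluster averages.
4. **Evaluation.** Pre vs post separation per dataset via ROC-AUC
   (Mann–Whitney formulation, positive class = post/trained; AUC < 0.5 ⇒
   post scores lower ⇒ M1 direction) and Welch's two-sample t-test.
5. **Signature refinement.** Model genes are screened by per-gene AUC on a
   muscle exercise dataset; |AUC − 0.5| ≥ 0.2 selects, AUC > 0.5 → Group 1,
   < 0.5 → Group 2. The refined 25-gene muscle-resident signature
   (3 M1: APOL6, LIMK2, IL15; 22 M2) ships with the package
   (`packaged_muscle_signature()`).

A synthetic-cohort generator (`generate_cohort`, `generate_polarized_set`)
produces expression matrices with the bimodal, cluster-correlated structure
the method assumes, plus configurable pre→post shifts, missing data and
duplicate probes — so every stage is testable without downloads.

## Worked example

```python
import macpolar as mp

# a synthetic "immediate exercise" cohort: M1-direction shift of 1 log2 unit
cohort = mp.generate_cohort(mp.SyntheticConfig(
    n_pre=20, n_post=20, shift=-1.0, shift_arm="M1", seed=42))

comparison = mp.evaluate_dataset(
    cohort.matrix, cohort.annotation, cohort.truth_model, label="immediate")
print(f"{comparison.label}: n={comparison.n_pre}+{comparison.n_post} "
      f"AUC={comparison.auc:.3f} t={comparison.t_stat:.2f} "
      f"p={comparison.p_value:.2e} significant={comparison.significant}")

signature = mp.packaged_muscle_signature()
print(f"signature: {len(signature)} genes "
      f"({(signature.entries.arm == 'M1').sum()} M1, "
      f"{(signature.entries.arm == 'M2').sum()} M2)")
```

prints

```
immediate: n=20+20 AUC=0.087 t=-6.51 p=1.67e-07 significant=True
signature: 25 genes (3 M1, 22 M2)
```

The AUC of 0.087 says nearly every post-exercise sample scores *below*
every pre-exercise sample — the composite score moved in the M1 direction,
recovering the implanted immediate-exercise effect; Welch's t confirms the
group difference. Real datasets run the same way from TSV or GEO
series-matrix files:

```bash
macpolar run --matrix expr.tsv --annotation samples.tsv \
             --model model.tsv --out results/
macpolar score --matrix expr.tsv --out scores.tsv   # packaged 25-gene signature
```

`macpolar --help` lists the other stages (normalize, binarize, relations,
evaluate, signature, simulate, meta).

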