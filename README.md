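# seroscreen

Protein-microarray autoantibody screening and diagnostic modelling for
rheumatoid arthritis (RA) cohorts.

About one third of RA patients lack anti-citrullinated protein antibodies
(ACPA), the established specific serology, and are hard to diagnose —
especially within the first two years of disease, when treatment matters
most. One route to new markers is a two-phase proteome-array screen: probe
sera on a genome-wide protein array printed in duplicate (Phase I), select
candidate autoantigens, re-measure them on a small focused array across a
full case/control cohort (Phase II), and finally combine the panel into a
classifier. `seroscreen` implements that workflow end to end as a tested,
reusable library plus CLI, driven by a synthetic cohort generator so every
stage is verifiable without access to patient data.

## What it computes

* **Array I/O and QC** — GAL/GPR-style text dialects; net signal
  `max(F532 − B532, 1)`; duplicate aggregation with relative percentage
  difference `RPD = |a−b| / ((a+b)/2) × 100`; scan-level QC (fraction of
  spots with fluorescence in [1000, 24000], fraction of duplicate pairs with
  RPD < 30%, both ≥ 90% to pass).
* **Hit calling** — a probe is positive for a serum iff *both* duplicate
  spots are present (net ≥ 3 × local background SD) and *no* duplicate is
  present on the blank or secondary-antibody-only reference arrays.
* **Candidate selection** — signal-to-noise ratio strictly > 13 and net
  signal strictly > 2.5 × the pooled-control net, in ≥ 2 case sera, with
  hit-positivity in 0 healthy controls.
* **Per-antibody diagnostics** — seropositivity cutoff = healthy-control
  mean + 2 SD; sensitivity/specificity; nonparametric (Mann–Whitney) AUC
  with DeLong 95% CI; early- vs established-stage prevalence (chi-square or
  Fisher's exact); Spearman/Pearson clinical correlation with Bonferroni
  correction; t-SNE cohort embedding.
* **Diagnostic classifier** — RBF-kernel SVM, powers-of-two grid search by
  4-fold cross-validated AUROC, recursive feature elimination ranking
  features by the margin-criterion change `|ΔJ|`,
  `J = ½ Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)`, when a feature's column is removed from the
  kernel with the dual coefficients held fixed; data-driven feature count;
  decision threshold anchored at 90% specificity on the training set with a
  cross-validated optimism correction; ACPA-stratified held-out evaluation
  and comparison against single citrullinated-peptide markers (CH-28,
  NH-26).

## Worked example

```python
from seroscreen import SimulationConfig
from seroscreen.pipeline import run_pipeline

res = run_pipeline(SimulationConfig(seed=1))
print("candidates:", len(res.candidates),
      "| informative recalled:", f"{res.informative_recall():.0%}")
top = res.diagnostics.iloc[0]
print("best antibody:", res.diagnostics.index[0],
      f"AUC {top['auc']:.3f}, sens {top['sensitivity_pct']}%,",
      f"spec {top['specificity_pct']}%")
ev = res.eval_report
print(f"model: {len(res.training.model.feature_ids)} features, "
      f"test AUROC {ev.auroc:.3f}, sens {ev.sensitivity:.1%}, "
      f"spec {ev.specificity:.1%}")
```

prints

```
candidates: 12 | informative recalled: 80%
best antibody: P00117 AUC 0.706, sens 33.0%, spec 96.9%
model: 12 features, test AUROC 0.910, sens 77.4%, spec 92.9%
```

Twelve of the 200 simulated antigens pass Phase I, all of them planted
informative antigens (12/15 recalled). The best single antibody reaches AUC
0.71 with high specificity but modest sensitivity — the familiar profile of
an RA autoantibody — while the 12-marker SVM panel raises held-out
sensitivity to 77% at the ~90% specificity the threshold was calibrated
for. ACPA-negative test cases are detected far less often (27%) than
ACPA-positive ones (88%), reflecting the attenuated signal planted in that
subgroup.

The same workflow runs from the shell against file artifacts:

```bash
seroscreen all --seed 1 --out runs/demo
```

## Layout

```
src/seroscreen/
  array_io.py     layouts, scans, manifests, intensity matrices
  simulate.py     synthetic cohort generator with planted ground truth
  screening.py    QC, hit calling, candidate selection (Phase I)
  diagnostics.py  cutoffs, ROC, prevalence, correlation, embedding (Phase II)
  model.py        RBF-SVM, kernel RFE, threshold calibration, evaluation
  pipeline.py     end-to-end orchestration (in memory)
  cli.py          stage-by-stage CLI over file artifacts
docs/methods.md   model assumptions, parameter choices, limitations
```
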