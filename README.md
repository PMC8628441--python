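# sepsisrules

Rule discovery and analysis for in-hospital mortality prediction in
sepsis-like ICU cohorts.

Severity scores and black-box classifiers sit at two unsatisfying extremes
of ICU mortality prediction: the former assume additive linear effects, the
latter predict well but explain little. This package implements the middle
road: mine a cohort for *rules* — conjunctions of threshold conditions such
as `Potassium.serum > 4.1 & Platelets <= 136.7` — that stratify death risk,
vet each rule statistically, and predict from the vetted set, so the model's
reasoning can be read directly. It is written for biostatisticians and
clinical-ML researchers who want an interpretable rule ensemble with a
survival-analysis audit trail, and it ships a synthetic cohort generator
with planted ground truth so the whole pipeline is testable without access
to protected clinical data.

## The method

A rule maps a patient vector to {0, 1} via `r(x) = prod_j 1{x_j in s_j}`
(1 = the patient *endorses* the rule). The pipeline has two phases:

**Rule discovery.** Candidate rules are read off the root-to-node paths of
a bootstrap random forest of shallow trees (depths cycling 1..3), then
pruned to a sparse subset by ℓ1-regularized logistic regression on the
patients × rules endorsement matrix:

    min_{w,b}  (1/N) Σ_i log(1 + exp(−y_i (wᵀ r(x_i) + b)))  +  λ‖w‖₁,

y ∈ {−1, +1}, intercept unpenalized. The tree count and λ are tuned by
stratified 10-fold cross-validation on misclassification, with the
one-standard-error rule for λ. Rules with nonzero weight survive; each
carries its support (fraction of patients endorsing it) and a direction
(sign of its weight: positive = risk-increasing).

**Rule analysis.** Every surviving rule is survival-screened: Kaplan–Meier
curves and a two-group log-rank test compare endorsers with non-endorsers
(deaths at their event day, survivors censored at discharge). A
*decomposition* step removes each condition in turn and re-tests; when the
complete rule's p-value beats every ablation's, the conditions are
synergistic. Rules that are significant, non-degenerate in support, and
synergistic feed a logistic *rule-endorsement* prediction model, evaluated
by 100 repeated stratified 70/30 splits (mean ± SD test AUC), DeLong tests
against baselines on a canonical split, and a calibration table. qSOFA
(SBP ≤ 100, RR ≥ 22, GCS < 15; one point each) is included as the clinical
comparator.

## Worked example

Generate a 2000-patient synthetic cohort whose death risk (prevalence ~1/3)
is driven by three planted rules, then run the full pipeline:

```python
import sepsisrules as sr

preds = sr.default_predictors(include_age=False)   # 14 ICU measurements
planted = (
    sr.PlantedRule(sr.parse_rule("GCS <= 8 & Bilirubin > 2"), 2.0),
    sr.PlantedRule(sr.parse_rule("Potassium.serum > 4.4 & Platelets <= 150"), 1.8),
    sr.PlantedRule(sr.parse_rule("pH.art <= 7.25 & Creatinine > 2"), 1.5),
)
spec = sr.CohortSpec(n=2000, predictors=preds, planted_rules=planted,
                     intercept=-2.0, seed=1)
cfg = sr.RunConfig(
    cohort=spec,
    fit=sr.FitConfig(n_trees_grid=(100,), n_lambda=30,
                     lambda_min_ratio=0.05, cv_folds=5),
    eval=sr.EvalConfig(n_repeats=100),
    output_dir="runs/demo", seed=1,
)
manifest = sr.run_pipeline(cfg)
print(manifest["n_rules_discovered"], manifest["n_rules_retained"],
      round(manifest["mean_auc"], 3))
```

This prints `9 6 0.79`: 9 rules discovered, 6 retained by the filter, and a
mean held-out AUC of 0.790 (SD 0.017) — against a Bayes ceiling of 0.782
for this generating process (`sr.bayes_auc(spec)`), so the fitted model is
at the information limit of the planted risk. The rule report
(`runs/demo/rule_report.csv`) shows the recovered structure; the top row
group reads:

```
rule_001 complete  Bilirubin > 1.833 & GCS <= 7.829   support 0.23  increasing  p 4.6e-48
rule_001 ablation  GCS <= 7.829                       support 0.28              p 4.2e-33
rule_001 ablation  Bilirubin > 1.833                  support 0.82              p 4.8e-04
```

i.e. the planted `GCS <= 8 & Bilirubin > 2` pattern, recovered with
thresholds at the tree-split resolution, and with the synergy signature —
the complete rule separates survival far better than either condition
alone. Each run also writes the cohort, the fitted ensemble JSON, the
prediction and calibration tables, and a manifest with config hash and
artifact checksums; re-running the same config reproduces identical
artifacts.

The same stages are available from the shell:

```sh
sepsisrules run --config run.yaml --seed 1 --output-dir runs/demo
sepsisrules simulate --config run.yaml --output-dir runs/demo
sepsisrules discover runs/demo/cohort.csv --config run.yaml --output-dir runs/demo
```

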