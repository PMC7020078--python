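"""Full modelling and validation chain for one clinical scale.

Stability-selected survivors enter a capped bidirectional stepwise OLS
(at most n/5 = 11 terms for 53 subjects); coefficients are then averaged
over bootstrap refits. The fitted equation is evaluated by leave-one-out
and five-fold cross-validation, and applied frozen to the drifted
follow-up records (blind validation), with a Friedman test comparing the
paired absolute errors on the follow-up subjects.
"""

import pspdti as p

config = p.CohortConfig.fast(seed=4)
table, records = p.generate_feature_table(config)
clinical = p.records_to_frame(records)
levels = sorted(clinical["protocol"].unique())
baseline = clinical[clinical["timepoint"] == "baseline"]
followup = clinical[clinical["timepoint"] == "followup"]

X = p.augment_with_covariates(table.data.loc[baseline.index], baseline, protocol_levels=levels)
y = baseline["UPDRS3"].astype(float)

result = p.bootstrap_select(X, y, B=150, tau=0.20, seed=21, target="UPDRS3")
survivors = p.cap_check(result, len(y))
step = p.stepwise_fit(X[survivors], y, cap=p.feature_cap(len(y)), target="UPDRS3")
model = p.bootstrap_coefficients(
    step.feature_names, X, y, B=200, seed=22, target="UPDRS3", template=step
)
print(model.to_equation())
print(f"\ntraining: n={model.training_n}, adjusted R2={model.adjusted_r2:.3f}, "
      f"F={model.f_statistic:.0f}")

loo = p.loocv(model.feature_names, X, y, "UPDRS3")
five = p.kfold_cv(model.feature_names, X, y, "UPDRS3", k=5, seed=23)
fu_X = p.augment_with_covariates(table.data.loc[followup.index], followup, protocol_levels=levels)
blind = p.blind_validate(model, fu_X, followup["UPDRS3"].astype(float))

for rep in (loo, five, blind):
    print(f"{rep.scheme:>9}: n={rep.n:2d}  mean adj R2={rep.mean_adjusted_r2:.3f}  "
          f"MAE={rep.mae:5.2f} ± {rep.mae_sd:.2f}  MAE%={rep.mae_pct:.1f} ± {rep.mae_pct_sd:.1f}")

# paired error comparison on the follow-up subjects
import pandas as pd

subj = followup["subject_id"]
errors = pd.DataFrame({
    "loocv": subj.map(loo.per_subject["error"].abs()).to_numpy(),
    "fivefold": subj.map(five.per_subject["error"].abs()).to_numpy(),
    "followup": blind.per_subject["error"].abs().to_numpy(),
}, index=followup.index)
stat, pval = p.friedman_compare(errors)
print(f"\nFriedman over paired |errors| (loocv, fivefold, followup): "
      f"chi2={stat:.2f}, p={pval:.4f}")
print(f"blind/loocv MAE ratio: {blind.mae / loo.mae:.2f} "
      "(inflated but below the three-fold regime)")
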