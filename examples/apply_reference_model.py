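"""Evaluate the bundled published severity equations.

The four reference models (UPDRS-III, PIGD, MHY, LEDD) are shipped as
data: eleven FA/MD percentile terms each, with unstandardized
coefficients. This example renders the LEDD equation, evaluates every
model at the origin of feature space (returning the published intercepts)
and on a plausible synthetic feature row.
"""

import numpy as np

import pspdti as p

models = p.bundled_reference_models()

print(models["LEDD"].to_equation())

zero = {name: 0.0 for m in models.values() for name in m.feature_names}
print("\nintercepts (all features zero):")
for target, model in models.items():
    print(f"  {target:>7}: {model.predict(zero):8.1f}")

# a plausible feature row: FA percentiles ~0.4, MD percentiles ~0.8e-3 mm^2/s
rng = np.random.default_rng(5)
row = {}
for model in models.values():
    for name in model.feature_names:
        metric = p.parse_feature_name(name).metric
        centre = 0.40 if metric == "FA" else 0.80
        row.setdefault(name, centre + rng.normal(0, 0.02))

print("\npredictions on a synthetic feature row (FA ~ 0.40, MD ~ 0.80):")
for target, model in models.items():
    print(f"  {target:>7}: {model.predict(row):8.1f}")
print("\nUPDRS-III is 0-108 points, PIGD 0-20, MHY stage 1-5, LEDD mg/day."
      "\nPredictions are unclipped equation values, as published.")
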