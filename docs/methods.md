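# Methods

This note documents the models, conventions and design choices behind
`pspdti`: what each stage computes, what the synthetic cohort generator
does and does not emulate, and the numerical decisions a maintainer would
otherwise have to reverse-engineer.

## Feature extraction

A subject contributes one FA and one MD volume on the atlas grid; all
spatial work (tensor fitting, co-registration, normalisation) is assumed
done upstream, and the package operates in voxel-index space only — no
resampling is implemented, and atlases on a different grid are rejected.
The parenchymal mask is applied before any statistic is computed: out-of-
mask voxels are flagged (stored as NaN) and never enter a percentile.
Masking an entire map away is an error; masking an entire *region* away
yields a missing marker for that region, and table assembly drops such
columns cohort-wide with a logged warning so downstream stages always see
a complete matrix.

Percentiles use the linear-interpolation order-statistic convention (the
"linear" definition: value at rank $1 + (n-1)p/100$, interpolating
between the two closest order statistics). The convention matters for
10th/90th percentiles of small regions, so it is fixed, documented and
tested against a brute-force sort-and-interpolate oracle; a single-voxel
region returns that voxel's value for every percentile. Feature names
follow the `{METRIC}{PCTL}_{label_code}` grammar and parse uniquely back
to (metric, percentile, region); covariate columns deliberately do not
parse, which is how the two kinds are distinguished everywhere.

## Stability selection

Selection is over bootstrap case resamples (n-of-n with replacement);
residual resampling is not offered. Within each replicate an L1-penalised
least-squares fit runs on standardized features, with the penalty chosen
by 5-fold cross-validation over a 50-point logarithmic grid anchored at
the smallest all-zero penalty (a fixed-penalty rule is available where
speed matters). Survival is `count >= ceil(tau * B)` — with B = 1000 and
tau = 0.20, at least 200 selections. Demographic covariates are penalised
exactly like imaging features; rows with a missing response are removed
listwise before resampling (the PIGD rule). The cap check enforces fewer
survivors than subjects by raising tau to the smallest value that
restores the bound, recording the adjustment.

A property worth knowing: with the CV-min penalty rule, a bootstrap
resample contains duplicated rows that fall on both sides of the inner CV
split, biasing the chosen penalty low. On pure-noise designs
(n = 53, p = 144) this yields a survivor fraction of roughly a third of
the candidates at tau = 0.20 rather than a conventionally "sparse" set.
Selection frequencies are therefore reported in full, and the test suite
logs false-discovery behaviour rather than asserting a sparsity theorem;
covariates are verified not to be *preferentially* selected relative to
noise features, which is the sound version of "only diffusion metrics
survive".

## Severity models

The model-size cap is $n/5$ rounded half away from zero (53 → 11). The
stepwise stage is classical bidirectional OLS: enter the candidate with
the smallest partial-F p-value if below `p_enter`, then drop any included
term above `p_remove`, until no move qualifies or the cap binds.
Entry/stay levels default to 0.15/0.15 — the defaults of the statistical
package tradition this procedure comes from — and ties break on smaller
p-value then lexicographic name, making fits reproducible to the bit.
Candidates that would make the design rank-deficient are skipped with a
warning. The stepwise direction ("bidirectional") and these thresholds
are design choices; forward- or backward-only variants are not offered.

Final coefficients are per-parameter arithmetic means over B
case-resampled OLS refits of the fixed term set (median by option);
replicates with singular designs are skipped and counted, and more than
50% singular is an error. Coefficients are reported on the original
feature scale, so an exported equation evaluates directly on raw feature
rows; `predict` is affine and unclipped — published equations of this
form are unbounded. Models serialise to a versioned JSON schema
(unknown fields rejected with their path) and render to a signed
term-per-line equation text.

The four bundled reference models are data, not fits: they cannot be
re-derived without the original clinical images and are shipped for
equation-evaluation tests and blind-application demos.

## Validation battery

Adjusted $R^2 = 1 - (1 - R^2)(n-1)/(n-p-1)$. MAE% divides each absolute
error by the scale maximum for bounded scales (108 / 20 / 5) — this is
the convention under which the published MAE and MAE% columns are
mutually consistent — and by the per-subject observed value for LEDD,
which has no ceiling (hence its much larger MAE% dispersion). Both
conventions are selectable per call.

Cross-validation refits *coefficients only*, on the term set selected
once from the full sample. This mirrors the published protocol, whose
cross-validated adjusted $R^2$ sits essentially at the training value —
incompatible with per-fold re-selection; re-running selection inside each
fold is the unbiased alternative and can be composed from the public API
(the per-fold engine accepts any feature list). "Mean adjusted $R^2$"
under CV is the mean over folds of the training-portion adjusted $R^2$,
the only reading available to leave-one-out. Fold assignment is a seeded
uniform random partition into near-equal folds, unstratified; LOOCV at
k = n coincides with k-fold per-subject predictions exactly. Folds whose
design is singular are skipped, counted and warned about; a run in which
every fold is skipped raises.

Blind validation applies the frozen baseline model, unchanged, to
follow-up rows (excluding rows with a missing score or feature, logged).
The Friedman comparison runs on paired absolute-error triples (LOOCV,
five-fold, follow-up) restricted to the follow-up subjects — the only
subjects for whom all three errors exist. The statistic uses average
ranks with tie correction; p comes from the chi-square approximation, or
from exhaustive within-block permutation (k!^n enumeration) for at most
9 subjects.

## The synthetic cohort generator

The generator's defaults *are* the study conditions: 53 baseline
subjects in three imaging protocols (19/11/23), 15 follow-up sessions,
exactly 3 missing baseline PIGD values, subtype strata in 27/15/7/4
proportion, and an atlas of 246 regions (24 in the fast configuration)
partitioned into contiguous equal blocks inside a one-voxel border mask,
with at least 27 voxels per region enforced.

Each subject draws a latent severity $s \sim U(0,1)$. Clinical scores
are affine links of severity — UPDRS-III $= 5 + 90s$, PIGD $= 1 + 17s$,
MHY $= 1 + 4s$, LEDD $= 200 + 900s$ — plus Gaussian noise (defaults
~5% of each link span), then clipped to the legal range, with MHY
rounded to half steps and PIGD to integers. The magnitudes were chosen
once to span realistic clinical ranges; no per-scale severity
correlations are published for cohorts like this, so the link slopes and
noise levels are plausibility choices, not fidelity claims. In the
noise-free diagnostic limit the links are exactly affine for the
continuous scales and affine up to the declared quantisation (0.5 and
1.0) for MHY and PIGD.

Five planted (region, metric) couplings shift regional voxel means by
$\text{slope} \times (s + d)$, where $d \sim N(0, 0.15)$ is a
subject-by-plant deviation, and scores are driven by the *effective*
severity $s + \overline{d}$. The deviations are the load-bearing design
choice: were regional means deterministic functions of the scalar $s$
alone, all plants would be perfectly collinear and no selector could
distinguish them — recovery of "all five plants" would be undefined. With
deviations, each plant carries signal no other region duplicates, and the
oracle regression of any score on the five plants has adjusted
$R^2 \ge 0.95$ at default noise. Because the three percentile columns of
one planted (region, metric) differ only by a near-constant offset,
recovery is scored at the (region, metric) level: a plant counts as found
when any of its percentile columns is selected.

Protocol effects are small additive offsets on MD only (±0.01 of
~0.65–0.95 × 10⁻³ mm²/s baselines), nuisance structure for verifying
that covariate screening does not promote protocol dummies. Follow-up
sessions shift severity by +0.15 (progressive disease), redraw plant
deviations and imaging noise (a new scan), and double the clinical score
noise — emulating fluctuating patient state and scanner drift between
sessions. The doubling is what produces the blind-validation regime of
inflated-but-bounded error: a correctly specified linear model is immune
to latent drift alone, so without it blind MAE would match LOOCV MAE.
Across the 20-seed study conditions the blind/LOOCV MAE ratio averages
≈ 2.8 with every seed above 1; a single 15-subject MAE carries ~20%
sampling error, so the sub-three-fold regime is a property of the ratio's
distribution, not of every individual draw.

Two feature routes share one subject stream per seed: the volume route
writes actual FA/MD grids for extraction through the imaging stage, and
the fast route draws each percentile from its asymptotic order-statistic
law, $\mu + z_p\sigma \pm N(0, \sigma\sqrt{p(1-p)/m}/\phi(z_p))$ for a
region of $m$ voxels. The fast route treats the three percentiles'
sampling noise as independent (in a real sample they are positively
correlated), and neither route simulates raw diffusion-weighted images,
gradient schemes, registration error or spatially structured noise —
passing tests therefore demonstrate the statistical machinery, not
robustness to real acquisition artefacts.

## Problem sizes and determinism

The test suite runs the full pipeline study at B = 200 bootstrap
replicates per stage on the 24-region cohort over 20 seeds, and unit
material at B = 40–200; the full-scale configuration (246 regions,
B = 1000) is exercised for feature-count arithmetic and is the documented
production setting. One master seed derives independent substreams per
(stage, scale) via hashed seed sequences (all below 2³¹), so any stage is
reproducible in isolation and a pipeline manifest replays byte-for-byte.

## Known limitations

Real-data mode expects pre-aligned NIfTI volumes and performs no spatial
processing; the generator's Gaussian, spatially unstructured noise is
optimistic; stability-selection frequencies under the CV-min penalty rule
are liberal (see above); and the bundled reference equations can be
evaluated but not re-estimated, since their source images are not
available.
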