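"""Score a signature on a patient cohort and test its prognostic value.

Simulates a 703-patient cohort whose hazard rises with a planted
20-gene signature score (hazard ratio 1.49 per score SD), then runs the
scoring stack: z-transformation, +1/-1 weighted combined score, Cox
regression on the continuous score, and Kaplan-Meier / log-rank after
median dichotomization.
"""

import numpy as np

import epiprog as ep

signature = ep.Signature(
    "metastasis-like",
    up_genes=frozenset({(f"u{i:02d}", "") for i in range(10)}),
    down_genes=frozenset({(f"d{i:02d}", "") for i in range(10)}),
)

true_hr = 1.49
cohort = ep.simulate_cohort(
    n_patients=703, signature=signature, beta_per_sd=np.log(true_hr),
    censor_rate=0.2, seed=21,
)

z = ep.zscore(cohort.matrix)
scores = ep.signature_score(z, signature, mode="combined")["combined_score"]

fit = ep.cox_fit(cohort.covariates["signature_score"], cohort.time, cohort.event)
print(f"patients: {fit.n}, events: {fit.n_events}")
print(f"Cox on continuous score: HR = {fit.hazard_ratio:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), Wald p = {fit.p_wald:.2g}")
print(f"planted HR per score SD: {true_hr}")

groups = ep.dichotomize_median(scores)
lr, curves = ep.km_logrank(groups, cohort.time, cohort.event)
print(f"median split {lr.group_sizes}: log-rank chi2 = {lr.logrank_chi2:.1f}, "
      f"p = {lr.p_logrank:.2g}")
print()
print("KM curve, high-score arm (first rows):")
print(curves["high"].head(5).to_string(index=False))

rho, p = ep.covariate_association(scores, cohort.covariates["signature_score"])
print(f"\nSpearman rho of combined score vs stored standardized score: {rho:.3f}")
# The Cox estimate fluctuates around the planted HR with an SE of ~0.07 on
# the log scale, so any single cohort can land a standard error or two away
# (across replicates the 95% CI covers the truth ~95% of the time; see
# epiprog.validation.cox_recovery).  The log-rank split is strongly
# significant, and the Spearman check confirms the stored covariate is the
# recomputed score (rho = 1).
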