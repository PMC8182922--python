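"""Repeated-cohort study: which estimator recovers the latent prevalence?

Generates many cohorts under MAR attrition (and under an MNAR mechanism where
impaired children respond exp(0.4) ~ 1.5x less), and reports each estimator's
mean bias against the simulation's latent prevalence, in percentage points.
A small number of replicate cohorts keeps this example quick; the
reproduction script runs the full-size study.
"""

from ltfu import mar_recovery_study, mnar_recovery_study

mar = mar_recovery_study(n_seeds=10, n_children=3000, m=10, n_iterations=5, seed=0)
print("MAR attrition (response driven by social covariates only):")
print(f"  complete-case bias {mar['complete_case_bias_pp']:+.2f} pp")
print(f"  MI bias            {mar['mi_bias_pp']:+.2f} pp")
print(f"  IPW bias           {mar['ipw_bias_pp']:+.2f} pp")

mnar = mnar_recovery_study(n_seeds=10, n_children=3000, m=10, n_iterations=5,
                           delta_true=0.4, seed=0)
print("\nMNAR attrition (impaired children respond ~1.5x less):")
print(f"  MAR-imputation bias    {mnar['mar_mi_bias_pp']:+.2f} pp")
print(f"  delta=0.4 imputation   {mnar['delta_adjusted_bias_pp']:+.2f} pp")

# Under MAR the complete-case estimate is biased low while MI and IPW are
# near-unbiased; under MNAR plain MI inherits part of the selection bias and
# the delta-adjusted imputation at the true offset removes it.
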