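"""Generate a calibrated synthetic very-preterm cohort and describe attrition.

The default configuration emulates a two-region (Portugal / UK) cohort of
survivors assessed at 2 years of corrected age: ~54% parental response, ~18%
latent impairment prevalence, social covariates driving non-response, and
~11% outcome missingness among responders.
"""

from ltfu import attrition_table, default_epice_like_config, derive_outcomes, generate_cohort

cfg = default_epice_like_config(n_children=1737, seed=1)
cohort = derive_outcomes(generate_cohort(cfg))

report = attrition_table(cohort)
print(report.frame()[["stratum", "n_total", "n_responders", "pct_responders",
                      "pct_outcome_missing_responders", "pct_complete_case"]]
      .to_string(index=False))

# Each row gives, per stratum: cohort size, responders and the response
# percentage, the share of responders whose outcome could not be scored, and
# the share of children with a fully observed baseline record.
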