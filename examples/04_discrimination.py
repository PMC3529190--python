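"""Age-specific concordance (AUC) of a model on a synthetic cohort.

The weighted concordance averages age-band AUCs with weights proportional
to band size; bands without both a case and a non-case are excluded.
"""

from gailsbsp import simulate_cohort, weighted_concordance

cohort = simulate_cohort(30_000, "s-gail-sbsp", "sg-overall", seed=11)
report = weighted_concordance(cohort, "s-gail-sbsp", "sg-overall")
print(report)
# Values around 0.6 are typical for questionnaire-factor breast-cancer
# risk models: calibration can be excellent while individual-level
# discrimination stays modest.
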