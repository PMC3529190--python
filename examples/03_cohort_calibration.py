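"""Calibration study on a synthetic screening cohort.

Simulates 30,000 women with the documented risk-factor prevalences and
outcomes drawn from the model's own hazard structure, then checks expected
vs observed cases by age band and the decile calibration curve — the
standard E/O validation workflow.
"""

from gailsbsp import (decile_calibration, group_calibration, predict_cohort,
                      simulate_cohort)

cohort = simulate_cohort(30_000, "s-gail-sbsp", "sg-overall", seed=2026)

report = group_calibration(cohort, "s-gail-sbsp", "sg-overall",
                           group_by="age-band")
print(report)
# E/O near 1 per band and a non-significant chi-square indicate the
# predictions reproduce the simulated incidence.

pred = predict_cohort(cohort, "s-gail-sbsp", "sg-overall")
deciles = decile_calibration(pred["p_breast_cancer"],
                             cohort["case_status"].astype(int))
print("\ndecile calibration (1 = lowest predicted risk):")
print(deciles.to_string(index=False))
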