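"""Project one woman's 5-year absolute invasive breast-cancer risk.

A 50-year-old Singaporean-Chinese woman, menarche at age 12-13, first
live birth at 25-29, no affected first-degree relatives.
"""

from gailsbsp import (RawRecord, absolute_risk, builtin_coefficients,
                      builtin_rate_table, make_profile)

record = RawRecord(id="example", entry_age=50, ethnicity="sg-chinese",
                   age_menarche=13, age_first_live_birth=27,
                   n_first_degree_relatives=0)
profile = make_profile(record, model="s-gail-sbsp")

proj = absolute_risk(profile,
                     builtin_coefficients("s-gail-sbsp"),
                     builtin_rate_table("sg-chinese"),
                     h=5)

print(f"relative risk (age <50 / >=50): {proj.r_under50:.3f} / {proj.r_50plus:.3f}")
print(f"P(invasive breast cancer within 5y): {proj.p_breast_cancer:.4%}")
print(f"P(death from other causes first):    {proj.p_other_death:.4%}")
print(f"P(neither event):                    {proj.p_event_free:.4%}")
# The three probabilities partition certainty: the competing-risks
# projection counts a woman as a case only if cancer strikes before death
# from another cause and before the horizon.
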