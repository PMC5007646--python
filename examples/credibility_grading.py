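"""Grade the credibility of the pooled GSTM1/ATDH association.

Computes the combined sample's power to detect the pooled odds ratio,
the false-positive report probability across priors, and the Venice
interim criteria (amount of evidence / replication / bias protection).
"""

from driverscan import (
    fprp, genotype_totals, load_fixture, pool, two_proportion_power, venice_grade,
)

studies = load_fixture("gstm1_atdh")
totals = genotype_totals(studies)
pooled = pool(studies)

p0 = totals["control_present"] / totals["n_controls"]
power = two_proportion_power(totals["n_cases"], totals["n_controls"],
                             p0, pooled.pooled_or)
print(f"{totals['n_cases']} cases / {totals['n_controls']} controls, "
      f"control present-genotype prevalence {p0:.4f}")
print(f"power to detect OR {pooled.pooled_or:.2f} at alpha 0.05: {power:.3f}")

# FPRP at the observed significance, powered at a plausible alternative OR 0.6
power_alt = two_proportion_power(totals["n_cases"], totals["n_controls"],
                                 p0, 0.6, alpha=pooled.p)
for prior in (0.05, 0.01, 0.001):
    print(f"FPRP at prior {prior}: {fprp(pooled.p, power_alt, prior):.3f}")

report = venice_grade(
    int(totals["n_minor"]), pooled.i2,
    bias_checks={"robust_to_first_study": True},
    power=power,
)
print(f"n_minor = {report.n_minor} (subjects with the least frequent genotype)")
print(f"Venice grades: amount {report.grade_amount}, replication "
      f"{report.grade_replication}, bias {report.grade_bias} "
      f"-> {report.overall} cumulative evidence")

# Grade A amount (n_minor > 1000) and A/B replication (I2 <= 50%) with at
# least one passing bias check yields "moderate" overall credibility:
# the association is well supported but heterogeneity keeps it below "strong".
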