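"""Agreement statistics between two measurement routes.

Simulates two raters measuring lumbar lordosis on the same 63 subjects
(the second with small independent error), then computes the instruments
used to validate automated measurement: Bland-Altman limits of agreement,
the MAE/Pearson summary, a success-rate curve, and ICC(2,1) with its 95%
confidence interval.  With 1-degree rater noise the ICC lands near 0.99
and about 95% of differences fall inside the limits of agreement.
"""

import numpy as np

from spinemetrics import agreement_summary, bland_altman, icc_2_1, success_curve

rng = np.random.default_rng(7)
truth = rng.normal(-49.7, 14.3, 63)          # lumbar lordosis cohort, degrees
rater_a = truth + rng.normal(0, 1.0, 63)
rater_b = truth + rng.normal(0, 1.0, 63)

ba = bland_altman(rater_a, rater_b)
print(f"Bland-Altman: mean diff {ba.mean_diff:+.2f} deg, "
      f"limits [{ba.loa_lower:+.2f}, {ba.loa_upper:+.2f}]")

summary = agreement_summary(rater_a, rater_b)
print(f"MAE {summary.mae:.2f} deg, SD of AE {summary.sd_ae:.2f}, "
      f"r {summary.r:.3f}, R^2 {summary.r2:.3f}")

curve = success_curve(np.abs(rater_a - rater_b))
print(f"success rate at 3.5 deg: {curve.rates[curve.thresholds == 3.5][0]:.2f}")

icc = icc_2_1(np.column_stack([rater_a, rater_b]))
print(f"ICC(2,1) {icc.icc:.3f} (95% CI {icc.ci_lower:.3f}-{icc.ci_upper:.3f}, "
      f"p {icc.p_value:.2e})")
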