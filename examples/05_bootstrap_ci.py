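"""Percentile-bootstrap confidence interval for subject-level accuracy.

With only tens of subjects, a point accuracy like 23/28 = 82.1% carries wide
uncertainty.  Resampling the 28 per-subject right/wrong outcomes with
replacement 2000 times and taking the 2.5th/97.5th percentiles of the
resampled accuracy gives the 95% interval; bounds land on multiples of
100/28 because every resampled accuracy is k/28.
"""

from eegclassify.evaluation import bootstrap_ci

outcomes = [1] * 23 + [0] * 5  # 23 of 28 subjects classified correctly
lo, hi = bootstrap_ci(outcomes, B=2000, level=0.95, seed=1)
print(f"subject-level accuracy: {100 * 23 / 28:.2f}% (23/28)")
print(f"95% percentile bootstrap CI: [{lo:.2f}%, {hi:.2f}%]  (B = 2000)")

outcomes84 = [1] * 65 + [0] * 19  # 65 of 84 subjects correct
lo2, hi2 = bootstrap_ci(outcomes84, B=2000, level=0.95, seed=2)
print(f"larger cohort, 65/84 = {100 * 65 / 84:.2f}%: "
      f"CI [{lo2:.2f}%, {hi2:.2f}%]")
print("wider cohorts give narrower intervals; the quantum is 100/n")
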