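"""Group comparisons from printed summary statistics and percent changes.

Reproduces the arithmetic a reader can do from a published group table:
a Welch test from per-group (mean, SE, n), and percent-decrease
magnitudes from pairs of group means.
"""

from cnvcircuits import percent_change, percent_change_magnitude, welch_from_summary

# Whole-cohort self-stimulatory-behavior item: 47 normal-microarray
# subjects (2.79 +/- 0.158) vs 90 CNV subjects (2.39 +/- 0.107).
t, df, p = welch_from_summary(2.79, 0.158, 47, 2.39, 0.107, 90)
print(f"inter-group contrast: t = {t:.3f}, df = {df:.1f}, p = {p:.4f}")
print("  -> significant at 0.05: the CNV group scores lower on this item\n")

# Alpha-band EEG power in the interneuron-specific knockout mice:
# 73 uV^2 vs 112 uV^2 in controls.
print(f"alpha power change: {percent_change(112, 73):+.1f}% "
      f"(magnitude rounds to {percent_change_magnitude(112, 73)}%)")

# Brain weight at weaning: 0.37 g in knockouts vs 0.41 g in controls.
print(f"brain weight change: {percent_change(0.41, 0.37):+.1f}% "
      f"(magnitude rounds to {percent_change_magnitude(0.41, 0.37)}%)")
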