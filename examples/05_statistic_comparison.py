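"""Which envelope statistic detects a just-noticeable gain change?

Simulates pairs of exemplars at the standard gain (A=1) and at the
71%-correct signal gain (A=1.65), and reports how reliably each candidate
statistic separates them, as a z-score (mean difference / sd of
differences). A reduced repeat count keeps this quick; the acceptance
script runs the full 2000 pairs.
"""

from stochtex.experiments import run_zscore_comparison

report = run_zscore_comparison(seed=5, n_reps=200)
m = report.metrics
print(f"exemplar pairs: {m['n_reps']}")
print(f"z(across-channel SMD) = {m['z_across_smd']:.3f}")
print(f"z(envelope skew)      = {m['z_skew']:.3f}")
print(f"z(envelope kurtosis)  = {m['z_kurtosis']:.3f}")
print(f"mean across-SMD difference = {m['mean_across_smd_diff']:.4f} "
      f"(sd {m['sd_across_smd_diff']:.4f})")
print(
    "\nOnly the across-channel SMD moves reliably with the gain parameter;"
    "\nthe higher-order moments of the (compressed) envelope barely budge,"
    "\nso a listener tracking skew or kurtosis could not do the task."
)
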