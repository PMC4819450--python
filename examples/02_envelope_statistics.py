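"""Auditory-model summary statistics as a function of comodulation.

Synthesizes a few tokens per comodulation value, runs the gammatone
auditory model and prints the three summary statistics plus the prediction
of the across-channel SMD from the within-channel SMD and the mean
correlation.
"""

import numpy as np

from stochtex import (
    FilterbankConfig,
    TextureParams,
    predict_across_smd,
    summary_stats,
    synthesize,
)

fb = FilterbankConfig()
print("  C   within  across  corr    predicted-across")
for c in (0.0, 0.25, 0.5, 0.75, 1.0):
    vals = []
    for seed in range(4):
        tok = synthesize(TextureParams(A=5.5, B=1.5, f0=34.0, C=c,
                                       duration=1.0, seed=100 + seed))
        s = summary_stats(tok.samples, fb)
        vals.append([s.within_smd, s.across_smd, s.across_corr])
    w, a, r = np.mean(vals, axis=0)
    pred = predict_across_smd(w, r, fb.n_channels)
    print(f" {c:4.2f}  {w:.3f}   {a:.3f}   {r:.3f}   {pred:.3f}")

print(
    "\nAs C rises, band envelopes synchronize: the mean cross-channel"
    "\ncorrelation and the modulation depth of the summed envelope grow"
    "\nsharply, while the per-channel depth grows only via carrier overlap."
    "\nThe last column shows across ~= within * sqrt((1+(N-1)r)/N)."
)
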