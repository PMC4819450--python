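# stochtex

Stochastic sound-texture synthesis, auditory envelope statistics, and a
fully simulated texture-discrimination psychophysics pipeline.

Sound textures — rain, wind, fire, running water — are stationary stochastic
sounds that listeners identify from the time-averaged statistics of their
sub-band envelopes rather than from individual events. `stochtex` implements
a four-parameter generative texture model, the auditory-model statistics that
describe what such sounds look like after cochlear filtering, and a
simulated listener that replaces human subjects so the complete experimental
chain — synthesis, discrimination trials, psychometric fitting,
dissimilarity ratings, multidimensional scaling, variance partitioning — can
be run end to end on a laptop. It is aimed at auditory researchers who want
a reproducible sandbox for envelope-statistic psychophysics.

## The model

A texture token is a sum of narrowband noise carriers (two-pole resonators,
centre frequencies ~500–4000 Hz on an even auditory scale), each multiplied
by a non-negative stochastic modulator built in three stages:

1. **Low-pass Gaussian noise** `x(t)` with amplitude spectrum
   `W(f) = A·exp(−f²/(2f₀²))` — gain `A` sets the standard deviation of
   `x`, and `f₀` the modulation rate (characteristic time-scale `t₀ = 1/f₀`).
2. **Softplus nonlinearity** `a(t) = log(1 + exp(x(t) − B))` — offset `B > 0`
   controls how much of the modulator sits near zero ("sparsity").
3. **Comodulation mixing** `mₙ(t) = C·a₀(t) + (1−C)·aₙ(t)` — weight
   `C ∈ [0, 1]` interpolates between independent band envelopes (`C = 0`)
   and one shared envelope for all bands (`C = 1`).

All tokens are normalized to a common rms, so the four parameters
(`A, B, f₀, C`) manipulate only the envelope statistics.

On the analysis side, a 24-channel fourth-order gammatone filterbank with
envelope extraction (half-wave rectification, low-pass smoothing, power-law
compression, group-delay alignment) yields an envelope matrix from which
three summary statistics are computed:

* **within-channel SMD** — statistical modulation depth σ/μ per channel
  envelope, averaged over channels;
* **across-channel SMD** — σ/μ of the summed channel envelopes;
* **across-channel correlation** ρ̄ — mean Pearson correlation over all
  distinct channel pairs.

For channels sharing one mean and one variance these are linked exactly by
`across = within · sqrt((1 + (N−1)ρ̄)/N)` → `within · sqrt(ρ̄)` for large N
(`predict_across_smd`).

## Worked example

```python
import numpy as np
from stochtex import TextureParams, synthesize, summary_stats

for c in (0.0, 0.5, 1.0):
    tok = synthesize(TextureParams(A=5.5, B=1.5, f0=34.0, C=c,
                                   duration=1.0, seed=7))
    s = summary_stats(tok.samples)
    print(f"C={c:3.1f}  within={s.within_smd:.3f}  "
          f"across={s.across_smd:.3f}  corr={s.across_corr:.3f}")
```

prints

```
C=0.0  within=0.473  across=0.224  corr=0.181
C=0.5  within=0.474  across=0.332  corr=0.459
C=1.0  within=0.827  across=0.760  corr=0.798
```

Increasing the comodulation weight leaves each band's statistics nominally
unchanged but makes the bands rise and fall together: the across-channel
correlation and the modulation depth of the summed envelope grow sharply,
while the within-channel SMD creeps up only through carrier overlap — the
dissociation that makes across-channel cues experimentally identifiable.

The `examples/` directory holds one short script per capability (synthesis,
analysis, psychometric simulation, the rating/MDS study, and the statistic
comparison); each prints the numbers it computes together with a line on
what they mean.

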