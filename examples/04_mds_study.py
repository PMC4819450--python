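"""End-to-end simulated rating study: JNDs -> 9 stimuli -> MDS -> variance.

One simulated listener measures psychometric functions for the gain and
comodulation parameters, builds the 3 x 3 stimulus set from the fitted
JNDs, rates all stimulus pairs, embeds the dissimilarity matrix with MDS
and partitions the dominant dimension's variance among the candidate
auditory cues.
"""

import warnings

from stochtex.experiments import run_full_pipeline
from stochtex.observer import ObserverConfig

warnings.filterwarnings("ignore", category=UserWarning)

report = run_full_pipeline(
    seed=11,
    listener_count=1,
    duration=1.0,
    n_rating_repeats=3,
    observer=ObserverConfig(rating_gain=0.5, rating_noise_sd=0.01),
    mds_metric=True,
)

listener = report.metrics["per_listener"][0]
print(f"fitted JNDs: gain A = {listener['jnd_A']:.2f}, comodulation C = {listener['jnd_C']:.2f}")
print(f"stimulus values: A = {[round(v, 2) for v in listener['a_values']]}, "
      f"C = {[round(v, 2) for v in listener['c_values']]}")
print(f"MDS stress by dimensionality: "
      f"{ {k: round(v, 4) for k, v in listener['stress'].items()} }")
print("variance of dimension 1 accounted for (%):")
for stat, pct in report.metrics["variance_partition_pct"].items():
    print(f"  {stat:12s} {pct:5.1f}")
print(f"ranking: {report.metrics['ranking']}")
print(
    "\nThe observer rated pairs using the across-channel SMD, and the"
    "\nvariance partition recovers it (with the within-channel SMD and the"
    "\ncross-channel correlation close behind - the three cues are nearly"
    "\ncollinear over such stimulus sets)."
)
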