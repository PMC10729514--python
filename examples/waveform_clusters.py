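"""Cluster breath waveforms into shape categories and track prevalence.

Samples 400 resampled breaths from the four archetypes (sniff, small tidal,
large tidal, sigh), clusters them with silhouette-selected k-means, and then
shows how a planted shift of breath mass from small- to large-tidal breaths
is read out as prevalence ratios relative to the reference session —
mirroring how post-injury waveform redistribution is quantified against the
pre-injury recording.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from cordquant.pleth import cluster_waveforms, prevalence_relative
from cordquant.simulate import BreathSpec, archetype_matrix

kwargs = dict(jitter_amplitude=0.02, jitter_duration=0.02)
pre_mix = {"sniff": 0.15, "small_tidal": 0.55, "large_tidal": 0.25, "sigh": 0.05}
post_mix = {"sniff": 0.15, "small_tidal": 0.35, "large_tidal": 0.45, "sigh": 0.05}

pre_rows, pre_labels = archetype_matrix(BreathSpec(mix=pre_mix, **kwargs), 400, seed=0)
post_rows, _ = archetype_matrix(BreathSpec(mix=post_mix, **kwargs), 400, seed=1)

pre_model = cluster_waveforms(pre_rows, (2, 8), seed=0)
post_model = cluster_waveforms(post_rows, (2, 8), seed=0)
print(f"categories found: pre {pre_model.k}, post {post_model.k}")
print(f"pre-session ARI vs planted archetypes:"
      f" {adjusted_rand_score(pre_labels, pre_model.assignments):.2f}")
print("pre prevalence: ", np.round(np.sort(pre_model.prevalence)[::-1], 2))

ratios = prevalence_relative(post_model, pre_model)
print("prevalence ratios (post/pre, by matched category):",
      {k: round(float(v), 2) for k, v in sorted(ratios.items())})
print(
    "\nFour categories are recovered with near-perfect agreement to the\n"
    "planted labels. The ratio well below 1 is the small-tidal category and\n"
    "the ratio near 1.8 the large-tidal one: the planted 0.20 shift of\n"
    "breath mass, read out purely from waveform shape."
)
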