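"""Segment breaths and compute ventilation for baseline vs challenge.

Generates a one-minute baseline trace from the archetype library and a
challenge trace with 1.5x amplitudes (mimicking a hypoxic-hypercapnic gas
challenge), then reports tidal volume, rate, minute ventilation and the
challenge/baseline ratios.
"""

import dataclasses

from cordquant.pleth import challenge_response, segment_breaths, ventilation_summary
from cordquant.simulate import DEFAULT_ARCHETYPES, BreathSpec, make_flow_trace

baseline_spec = BreathSpec(duration_s=60, seed=0)
challenge_arch = {
    name: dataclasses.replace(a, amplitude_ml_s=1.5 * a.amplitude_ml_s)
    for name, a in DEFAULT_ARCHETYPES.items()
}
# same seed as baseline: the breath sequence matches, only amplitudes differ
challenge_spec = BreathSpec(duration_s=60, archetypes=challenge_arch, seed=0)

for label, spec in [("baseline", baseline_spec), ("challenge", challenge_spec)]:
    trace, truth = make_flow_trace(spec, condition=label)
    breaths = segment_breaths(trace)
    summary = ventilation_summary(breaths, trace, 60.0)
    print(f"{label:<10} {len(breaths):3d} breaths | TV {summary.tv_ml:.2f} mL |"
          f" RR {summary.rr_bpm:.0f} /min | MV {summary.mv_ml_min:.0f} mL/min")
    if label == "baseline":
        base = summary
    else:
        ratios = challenge_response(base, summary)
        print("challenge/baseline ratios:",
              {k: round(v, 2) for k, v in ratios.items()})
print(
    "\nMV = TV x RR by construction. The TV ratio near 1.5 recovers the\n"
    "planted challenge amplitude gain: the segmentation integrates the\n"
    "positive-flow phase of each breath, so amplitude scaling passes through\n"
    "to volume."
)
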