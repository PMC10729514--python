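"""Detect and stratify neurons on a synthetic section with known truth.

Plants small (putative interneuron) and large (putative motor neuron) somata
on both sides of the canal, detects them on the flat-fielded NeuN channel,
and compares the per-quadrant, per-size-class counts against the generator's
ground truth.
"""

import numpy as np

from cordquant.image_prep import flat_field, orient_section, quadrant_masks
from cordquant.section_quant import detect_neurons, detections_to_frame, neuron_count_table
from cordquant.simulate import SectionSpec, make_section, random_cells

rng = np.random.default_rng(0)
cells = random_cells(8, 6, shape=(256, 256), channel="neun", rng=rng)
spec = SectionSpec(seed=0, cells=tuple(cells))
channels, truth = make_section(spec)

record = orient_section(channels, spec.canal(), 0.0, "right")
detections = detect_neurons(
    flat_field(record.channels["neun"]),
    threshold=4000.0,  # half the soma amplitude
    exclusion=None,
    quadrants=quadrant_masks(record),
    pixel_size_um=record.pixel_size_um,
)
frame = detections_to_frame(detections, animal="demo", position_um=500.0)
table = neuron_count_table(frame, windows={"caudal": (0.0, 2000.0)})
print(table[table["count"] > 0].to_string(index=False))

true_counts = truth.count_table()
print(f"\ndetected {len(detections)} objects;"
      f" ground truth plants {sum(true_counts.values())} countable cells")
print(
    "\nSmall = 23-115 um^2, large = 116-345 um^2 (rasterized disk areas).\n"
    "On a noise-free section the detected table equals the planted truth\n"
    "exactly — the closed loop behind the count-recovery tests."
)
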