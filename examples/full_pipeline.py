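"""Run the whole pipeline on a small synthetic cohort.

Generates an intact and an injured ("sci") group — the injured animals carry
a planted 2x ipsilesional IBA1 gain, a damage region and vacuoles — then
quantifies every section and trace and runs the group statistics.  Outputs
land in ./pipeline_demo/.
"""

import pandas as pd

from cordquant.pipeline import run_pipeline

config = {
    "synthetic": {
        "groups": {
            "intact": {"n": 3},
            "sci": {
                "n": 3,
                "effects": {"iba1_ipsi_gain": 2.0, "vacuoles_ipsi": 4, "damage_ipsi": True},
            },
        },
        "n_sections": 3,
        "epicenter_index": 1,
    },
    "pleth": {"window_s": 30.0},
}

out = run_pipeline(config, out_dir="pipeline_demo", seed=1)
print("results in", out)

density = pd.read_csv(out / "density.csv")
ipsi = density[(density["channel"] == "iba1") & (density["side"] == "ipsi")]
print("\nipsilesional IBA1 optical density by group:")
print(ipsi.groupby("group")["mean_above"].mean().round(0).to_string())

stats = pd.read_csv(out / "group_stats.csv")
print("\ngroup comparisons:")
print(stats[["outcome", "omnibus_test", "omnibus_p", "posthoc_family"]].to_string(index=False))
print(
    "\nThe sci group's elevated ipsilesional IBA1 OD is the planted 2x\n"
    "neuroinflammation effect coming back out of the full image pipeline;\n"
    "every table row carries the run_id linking it to the manifest's input\n"
    "hashes."
)
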