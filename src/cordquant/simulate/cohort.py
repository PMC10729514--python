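"""On-disk synthetic cohorts: section TIFFs, flow CSVs and ground truth.

``make_cohort`` renders a study-design table (group x animal) into a
directory tree in the package's external-interface formats:

    out/
      design.csv                      copy of the design table
      landmarks.csv                   canal + rotation per section
      manifest.json                   seed, effects, generator parameters
      <animal>/
        <animal>_ser1_<slot>_<channel>.tif    16-bit grayscale, one per channel
        <animal>_ser1_<slot>_truth.json       per-section ground truth
        <animal>_baseline_trace.csv           time_s,flow
        <animal>_baseline_trace.json          sample_rate_hz, cal_ml_per_unit
        <animal>_challenge_trace.csv / .json

Group effects are multiplicative modifiers applied to the generators, keyed
by group name, e.g. ``{"SCI": {"iba1_ipsi_gain": 2.0, "damage_ipsi": true}}``.
Supported keys: ``iba1_ipsi_gain``, ``gfap_ipsi_gain``, ``neun_ipsi_loss``
(fraction of ipsilateral neurons removed), ``vacuoles_ipsi`` (count),
``damage_ipsi`` (plant one lesion-scale damage region at the epicenter
section), ``breath_amplitude_gain`` and ``challenge_gain`` (challenge-trace
amplitude relative to baseline).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ..image_prep import assign_position
from ..pleth import FlowTrace
from .flows import DEFAULT_ARCHETYPES, ArchetypeSpec, BreathSpec, BreathTruth, make_flow_trace
from .sections import (
    CHANNELS,
    DamageSpec,
    GroundTruth,
    SectionSpec,
    VacuoleSpec,
    make_section,
    random_cells,
    with_cells,
)

SERIES = "ser1"


def _scaled_archetypes(gain: float) -> dict[str, ArchetypeSpec]:
    return {
        name: dataclasses.replace(a, amplitude_ml_s=a.amplitude_ml_s * gain)
        for name, a in DEFAULT_ARCHETYPES.items()
    }


def _truth_to_json(truth: GroundTruth, spec: SectionSpec, position_um: float) -> dict:
    return {
        "position_um": position_um,
        "canal_px": list(truth.canal_px),
        "side_of_lesion": truth.side_of_lesion,
        "pixel_size_um": spec.pixel_size_um,
        "noise_sd": spec.noise_sd,
        "damage_regions": [
            {"center_px": list(d.center_px), "radius_px": d.radius_px, "intensity": d.intensity}
            for d in spec.damage_regions
        ],
        "vacuoles": [
            {"center_px": list(v.center_px), "radius_px": v.radius_px} for v in spec.vacuoles
        ],
        "damage_px": int(truth.damage_mask.sum()),
        "cells": [
            {
                "channel": c.channel,
                "centroid_px": list(c.centroid_px),
                "n_pixels": c.n_pixels,
                "area_um2": c.area_um2,
                "quadrant": c.quadrant.name.lower().replace("_", "-"),
                "size_class": c.size_class,
                "peak_intensity": c.peak_intensity,
                "overlaps": c.overlaps,
            }
            for c in truth.cells
        ],
    }


def _write_trace(trace: FlowTrace, truth: BreathTruth, stem: Path) -> None:
    pd.DataFrame({"time_s": trace.time_s(), "flow": trace.flow}).to_csv(
        stem.with_suffix(".csv"), index=False
    )
    sidecar = {
        "sample_rate_hz": trace.sample_rate_hz,
        "cal_ml_per_unit": trace.cal_ml_per_unit,
        "condition": trace.condition,
        "animal": trace.animal,
        "timepoint": trace.timepoint,
        "true_labels": truth.labels,
        "true_onsets": truth.onsets.tolist(),
        "true_tv_ml": truth.tv_ml.tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def read_trace(stem: str | Path) -> FlowTrace:
    """Load a trace written by :func:`make_cohort` (CSV + JSON sidecar)."""
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return FlowTrace(
        flow=df["flow"].to_numpy(),
        sample_rate_hz=meta["sample_rate_hz"],
        cal_ml_per_unit=meta["cal_ml_per_unit"],
        condition=meta.get("condition", "baseline"),
        animal=meta.get("animal", ""),
        timepoint=meta.get("timepoint", "pre"),
    )


def load_section(folder: str | Path, animal: str, slot: int) -> tuple[dict[str, np.ndarray], dict]:
    """Load one section's channel images and its ground-truth JSON."""
    folder = Path(folder)
    channels = {
        ch: tifffile.imread(folder / f"{animal}_{SERIES}_{slot}_{ch}.tif").astype(float)
        for ch in CHANNELS
    }
    truth = json.loads((folder / f"{animal}_{SERIES}_{slot}_truth.json").read_text())
    return channels, truth


def make_cohort(
    design: pd.DataFrame,
    out_dir: str | Path,
    seed: int = 0,
    *,
    group_effects: dict[str, dict] | None = None,
    section_template: SectionSpec | None = None,
    breath_template: BreathSpec | None = None,
    n_sections: int = 3,
    epicenter_index: int = 1,
    n_cells_per_side: tuple[int, int] = (4, 3),  # (small, large) per side, per channel
    overwrite: bool = False,
) -> Path:
    """Render a cohort design into an on-disk synthetic dataset.

    ``design`` needs columns ``group`` and ``animal``; each animal receives
    ``n_sections`` sections (section index 0.. with the epicenter at
    ``epicenter_index``) and a baseline + challenge flow trace.  Derived
    per-animal seeds keep every file deterministic in (design, seed).
    """
    if not {"group", "animal"} <= set(design.columns):
        raise ValueError("design must have 'group' and 'animal' columns")
    if len(design) == 0:
        raise ValueError("design table is empty")
    if design["animal"].duplicated().any():
        raise ValueError("duplicate animal ids in design")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    group_effects = group_effects or {}
    base_section = section_template or SectionSpec()
    base_breath = breath_template or BreathSpec()

    rng = np.random.default_rng(seed)
    landmark_rows = []
    manifest: dict = {"seed": seed, "group_effects": group_effects, "animals": {}}

    for _, row in design.iterrows():
        animal, group = str(row["animal"]), str(row["group"])
        eff = group_effects.get(group, {})
        animal_seed = int(rng.integers(0, 2**31 - 1))
        arng = np.random.default_rng(animal_seed)
        folder = out_dir / animal
        folder.mkdir(exist_ok=True)

        for idx in range(n_sections):
            slot = idx + 1
            position = assign_position(1, idx, epicenter_index)
            spec = dataclasses.replace(
                base_section, seed=int(arng.integers(0, 2**31 - 1)), cells=()
            )
            h, w = spec.image_size_px
            canal = spec.canal()
            damage: list[DamageSpec] = []
            if eff.get("damage_ipsi") and idx == epicenter_index:
                dc = (h * 0.5, w * 0.78 if spec.side_of_lesion == "right" else w * 0.22)
                damage.append(DamageSpec(center_px=dc, radius_px=28.0, intensity=15000.0))
            avoid = [(d.center_px, d.radius_px) for d in damage]

            cells = []
            for channel in ("iba1", "gfap", "neun"):
                gain_key = f"{channel}_ipsi_gain"
                for side in ("right", "left"):
                    is_ipsi = side == spec.side_of_lesion
                    n_small, n_large = n_cells_per_side
                    if channel == "neun" and is_ipsi and eff.get("neun_ipsi_loss"):
                        keep = 1.0 - float(eff["neun_ipsi_loss"])
                        n_small = int(round(n_small * keep))
                        n_large = int(round(n_large * keep))
                    peak = 8000.0
                    if is_ipsi:
                        peak *= float(eff.get(gain_key, 1.0))
                    cells.extend(
                        random_cells(
                            n_small,
                            n_large,
                            shape=spec.image_size_px,
                            channel=channel,
                            peak_intensity=peak,
                            rng=arng,
                            side=side,
                            canal_col=canal[1],
                            avoid=avoid,
                        )
                    )
            vacuoles = []
            n_vac = int(eff.get("vacuoles_ipsi", 0))
            for _ in range(n_vac):
                vr = float(arng.uniform(4.0, 7.0))
                vrow = float(arng.uniform(20, h - 20))
                lo = canal[1] + 15 if spec.side_of_lesion == "right" else 20
                hi = w - 20 if spec.side_of_lesion == "right" else canal[1] - 15
                vacuoles.append(
                    VacuoleSpec(center_px=(vrow, float(arng.uniform(lo, hi))), radius_px=vr)
                )
            spec = dataclasses.replace(
                spec, damage_regions=tuple(damage), vacuoles=tuple(vacuoles)
            )
            spec = with_cells(spec, cells)
            channels, truth = make_section(spec)
            for ch, img in channels.items():
                tifffile.imwrite(
                    folder / f"{animal}_{SERIES}_{slot}_{ch}.tif",
                    np.clip(img, 0, 65535).astype(np.uint16),
                )
            (folder / f"{animal}_{SERIES}_{slot}_truth.json").write_text(
                json.dumps(_truth_to_json(truth, spec, position))
            )
            landmark_rows.append(
                {
                    "animal": animal,
                    "series": SERIES,
                    "slot": slot,
                    "index": idx,
                    "canal_x": truth.canal_px[1],
                    "canal_y": truth.canal_px[0],
                    "rotation_deg": 0.0,
                }
            )

        amp_gain = float(eff.get("breath_amplitude_gain", 1.0))
        chal_gain = float(eff.get("challenge_gain", 1.5))
        bl_spec = dataclasses.replace(
            base_breath,
            archetypes=_scaled_archetypes(amp_gain),
            seed=int(arng.integers(0, 2**31 - 1)),
        )
        ch_spec = dataclasses.replace(
            base_breath,
            archetypes=_scaled_archetypes(amp_gain * chal_gain),
            seed=int(arng.integers(0, 2**31 - 1)),
        )
        bl_trace, bl_truth = make_flow_trace(bl_spec, condition="baseline", animal=animal)
        ch_trace, ch_truth = make_flow_trace(ch_spec, condition="challenge", animal=animal)
        _write_trace(bl_trace, bl_truth, folder / f"{animal}_baseline_trace")
        _write_trace(ch_trace, ch_truth, folder / f"{animal}_challenge_trace")

        manifest["animals"][animal] = {
            "group": group,
            "seed": animal_seed,
            "n_sections": n_sections,
            "epicenter_index": epicenter_index,
        }

    design.to_csv(out_dir / "design.csv", index=False)
    pd.DataFrame(landmark_rows).to_csv(out_dir / "landmarks.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
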