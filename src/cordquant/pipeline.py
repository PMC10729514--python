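"""End-to-end orchestration: synthesis -> quantification -> statistics.

``run_pipeline`` takes a configuration (dict or YAML path), optionally
generates a synthetic cohort, quantifies every section (optical density,
neuron counts, vacuolization), analyses every flow trace (ventilation
metrics and waveform clusters), tabulates the gas conditions of the exposure
arms, and runs the configured group comparisons.  All outputs are tidy CSV
tables plus a JSON manifest holding the seed, the full configuration, a
configuration hash and a SHA-256 per input file; every results table carries
the manifest's ``run_id`` so each number is traceable to its inputs.

Stage failures raise :class:`PipelineError` tagged with the stage name;
tables written before the failure are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gas, pleth, section_quant, stats
from .image_prep import (
    assign_position,
    flat_field,
    orient_section,
    quadrant_masks,
    read_landmarks,
    side_masks,
)
from .section_quant import (
    contralesional_threshold,
    detect_damage,
    detect_neurons,
    detections_to_frame,
    mirrored_roi,
    neuron_count_table,
    optical_density,
    vacuole_quant,
)
from .simulate import BreathSpec, SectionSpec, load_section, make_cohort, read_trace

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "groups": {
            "intact": {"n": 2},
            "sci": {
                "n": 2,
                "effects": {"iba1_ipsi_gain": 2.0, "vacuoles_ipsi": 4, "damage_ipsi": True},
            },
        },
        "n_sections": 3,
        "epicenter_index": 1,
        "noise_sd": 0.0,
        "breath_duration_s": 60.0,
    },
    "quantify": {
        "structuring_radius_px": 25,
        "neuron_threshold": {"mode": "contralesional"},
        "density_channels": ["iba1", "gfap"],
    },
    "pleth": {"window_s": 30.0, "k_range": [2, 6], "n_points": 64},
    "stats": {
        "outcomes": {
            "iba1_od_ipsi": {"posthoc": "tukey"},
            "tv_ml": {"posthoc": "dunnett", "control": "intact"},
        }
    },
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[
        :16
    ]


def _file_hashes(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("config", f"configuration must be a mapping, got {type(config)}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _stage_synth(cfg: dict, out: Path, seed: int) -> Path:
    s = cfg["synthetic"]
    rows = []
    for group, gcfg in s["groups"].items():
        for i in range(int(gcfg.get("n", 1))):
            rows.append({"group": group, "animal": f"{group}{i + 1:02d}"})
    design = pd.DataFrame(rows)
    effects = {g: gcfg.get("effects", {}) for g, gcfg in s["groups"].items()}
    data_dir = out / "data"
    make_cohort(
        design,
        data_dir,
        seed=seed,
        group_effects=effects,
        section_template=SectionSpec(noise_sd=float(s.get("noise_sd", 0.0))),
        breath_template=BreathSpec(duration_s=float(s.get("breath_duration_s", 60.0))),
        n_sections=int(s.get("n_sections", 3)),
        epicenter_index=int(s.get("epicenter_index", 1)),
        overwrite=True,
    )
    return data_dir


def _neuron_threshold(qcfg: dict, contra_threshold: float, image: np.ndarray) -> float:
    tcfg = qcfg.get("neuron_threshold", {"mode": "contralesional"})
    mode = tcfg.get("mode", "contralesional")
    if mode == "contralesional":
        return contra_threshold
    if mode == "fraction_of_max":
        return float(tcfg.get("fraction", 0.5)) * float(np.percentile(image, 99.9))
    raise PipelineError("quantify", f"unknown neuron_threshold mode {mode!r}")


def _stage_quantify(cfg: dict, data_dir: Path, out: Path, run_id: str) -> dict[str, pd.DataFrame]:
    qcfg = cfg["quantify"]
    radius = int(qcfg.get("structuring_radius_px", 25))
    landmarks = read_landmarks(data_dir / "landmarks.csv")
    design = pd.read_csv(data_dir / "design.csv")
    group_of = dict(zip(design["animal"].astype(str), design["group"].astype(str)))
    epicenter = json.loads((data_dir / "manifest.json").read_text())["animals"]

    density_rows, vac_rows, det_frames = [], [], []
    for (animal, slot), lm in landmarks.groupby(["animal", "slot"]):
        lm = lm.iloc[0]
        animal = str(animal)
        channels, truth = load_section(data_dir / animal, animal, int(slot))
        epi = int(epicenter[animal]["epicenter_index"])
        position = assign_position(1, int(lm["index"]), epi)
        record = orient_section(
            channels,
            (float(lm["canal_y"]), float(lm["canal_x"])),
            float(lm["rotation_deg"]),
            truth["side_of_lesion"],
            pixel_size_um=float(truth["pixel_size_um"]),
            animal=animal,
            slot=int(slot),
            section_index=int(lm["index"]),
            position_um=position,
        )
        flat = {
            ch: flat_field(img, radius)
            for ch, img in record.channels.items()
            if ch != "myelin"
        }
        sides = side_masks(record)
        quadrants = quadrant_masks(record)
        exclusion = detect_damage(record.channels, record.pixel_size_um)

        for ch in qcfg.get("density_channels", ["iba1", "gfap"]):
            roi = mirrored_roi(record.shape, record.canal_px, record.side_of_lesion)
            thr = contralesional_threshold(flat[ch], roi)
            for side_name, smask in sides.items():
                mean_above, n_above = optical_density(flat[ch], smask, thr)
                density_rows.append(
                    {
                        "run_id": run_id,
                        "animal": animal,
                        "group": group_of[animal],
                        "channel": ch,
                        "position_um": position,
                        "side": side_name,
                        "threshold": thr,
                        "mean_above": mean_above,
                        "n_above": n_above,
                    }
                )

        roi = mirrored_roi(record.shape, record.canal_px, record.side_of_lesion)
        neun_thr = _neuron_threshold(
            qcfg, contralesional_threshold(flat["neun"], roi), flat["neun"]
        )
        detections = detect_neurons(
            flat["neun"], neun_thr, exclusion, quadrants, record.pixel_size_um
        )
        frame = detections_to_frame(
            detections, animal=animal, section=int(slot), position_um=position
        )
        frame.insert(0, "run_id", run_id)
        det_frames.append(frame)

        for vr in vacuole_quant(
            record.channels["myelin"], sides, animal=animal, position_um=position
        ):
            vac_rows.append(
                {
                    "run_id": run_id,
                    "animal": animal,
                    "group": group_of[animal],
                    "position_um": vr.position_um,
                    "side": vr.side,
                    "n_vacuoles": vr.n_vacuoles,
                    "area_fraction": vr.area_fraction,
                }
            )

    density = pd.DataFrame(density_rows).sort_values(
        ["animal", "channel", "position_um", "side"]
    )
    detections = (
        pd.concat(det_frames, ignore_index=True)
        if det_frames
        else detections_to_frame([])
    )
    counts = neuron_count_table(detections, animals=sorted(group_of))
    counts.insert(0, "run_id", run_id)
    counts["group"] = counts["animal"].map(group_of)
    vacuoles = pd.DataFrame(vac_rows)

    density.to_csv(out / "density.csv", index=False)
    detections.to_csv(out / "detections.csv", index=False)
    counts.to_csv(out / "neuron_counts.csv", index=False)
    vacuoles.to_csv(out / "vacuoles.csv", index=False)
    return {"density": density, "detections": detections, "counts": counts, "vacuoles": vacuoles}


def _stage_pleth(cfg: dict, data_dir: Path, out: Path, run_id: str, seed: int) -> pd.DataFrame:
    pcfg = cfg["pleth"]
    window = float(pcfg.get("window_s", 300.0))
    design = pd.read_csv(data_dir / "design.csv")
    rows = []
    for _, drow in design.iterrows():
        animal = str(drow["animal"])
        folder = data_dir / animal
        summaries = {}
        for condition in ("baseline", "challenge"):
            trace = read_trace(folder / f"{animal}_{condition}_trace")
            breaths = pleth.segment_breaths(trace)
            summary = pleth.ventilation_summary(breaths, trace, window)
            summaries[condition] = summary
            if summary is None:
                continue
            entry = {
                "run_id": run_id,
                "animal": animal,
                "group": str(drow["group"]),
                "condition": condition,
                "n_breaths": summary.n_breaths,
                "tv_ml": summary.tv_ml,
                "rr_bpm": summary.rr_bpm,
                "mv_ml_min": summary.mv_ml_min,
            }
            if condition == "baseline":
                matrix = pleth.normalize_breaths(
                    breaths, trace, int(pcfg.get("n_points", 64))
                )
                model = pleth.cluster_waveforms(
                    matrix, tuple(pcfg.get("k_range", [2, 6])), seed=seed
                )
                entry["n_waveform_clusters"] = model.k
            rows.append(entry)
        if summaries["baseline"] and summaries["challenge"]:
            ratios = pleth.challenge_response(summaries["baseline"], summaries["challenge"])
            rows.append(
                {
                    "run_id": run_id,
                    "animal": animal,
                    "group": str(drow["group"]),
                    "condition": "challenge/baseline",
                    **ratios,
                }
            )
    vent = pd.DataFrame(rows)
    vent.to_csv(out / "ventilation.csv", index=False)
    return vent


def _stage_gas(out: Path, run_id: str) -> pd.DataFrame:
    rows = [
        {
            "run_id": run_id,
            "label": c.label,
            "fio2": c.fio2,
            "pressure_ata": c.pressure_ata,
            "inspired_po2_mmhg": c.inspired_po2_mmhg,
            "alveolar_po2_mmhg": c.alveolar_po2_mmhg,
            "dissolved_o2_ml_dl": c.dissolved_o2_ml_dl,
        }
        for c in gas.study_arms()
    ]
    table = pd.DataFrame(rows)
    table.to_csv(out / "gas_conditions.csv", index=False)
    return table


def _outcome_table(outcome: str, tables: dict[str, pd.DataFrame], vent: pd.DataFrame) -> pd.DataFrame:
    """Per-animal outcome values as a (group, value) tidy table."""
    if outcome.endswith("_od_ipsi") or outcome.endswith("_od_contra"):
        channel, _, side = outcome.rsplit("_", 2)
        side = {"ipsi": "ipsi", "contra": "contra"}[side]
        d = tables["density"]
        sub = d[(d["channel"] == channel.replace("_od", "")) & (d["side"] == side)]
        agg = sub.groupby(["animal", "group"])["mean_above"].mean().reset_index()
        return agg.rename(columns={"mean_above": "value"})
    if outcome == "tv_ml":
        sub = vent[vent["condition"] == "baseline"]
        return sub[["animal", "group", "tv_ml"]].rename(columns={"tv_ml": "value"})
    if outcome == "vacuole_fraction_ipsi":
        v = tables["vacuoles"]
        sub = v[v["side"] == "ipsi"]
        agg = sub.groupby(["animal", "group"])["area_fraction"].mean().reset_index()
        return agg.rename(columns={"area_fraction": "value"})
    raise PipelineError("stats", f"unknown outcome {outcome!r}")


def _stage_stats(
    cfg: dict, tables: dict[str, pd.DataFrame], vent: pd.DataFrame, out: Path, run_id: str
) -> pd.DataFrame:
    rows = []
    for outcome, ocfg in cfg["stats"].get("outcomes", {}).items():
        tidy = _outcome_table(outcome, tables, vent)
        try:
            comp = stats.group_compare(
                tidy,
                outcome=outcome,
                posthoc=ocfg.get("posthoc", "tukey"),
                control=ocfg.get("control"),
            )
        except ValueError as exc:  # e.g. too few observations at demo scale
            logger.warning("skipping outcome %s: %s", outcome, exc)
            continue
        row = {
            "run_id": run_id,
            "outcome": outcome,
            "omnibus_test": comp.omnibus_test,
            "omnibus_p": comp.omnibus_p,
            "posthoc_family": comp.posthoc_family,
        }
        for g, m in comp.group_means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "group_stats.csv", index=False)
    return table


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Run synthesis, quantification, breathing analysis and statistics.

    ``config`` may be a dict or a YAML path (merged over the defaults);
    ``out_dir`` and ``seed`` override the config's values.  Returns the
    results directory, which contains the CSV tables and ``manifest.json``.
    """
    cfg = load_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    run_seed = int(cfg["seed"])
    run_id = _config_hash(cfg)

    try:
        data_dir = Path(cfg["data_dir"]) if "data_dir" in cfg else _stage_synth(
            cfg, out, run_seed
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("synth", str(exc)) from exc
    if not (data_dir / "landmarks.csv").exists():
        raise PipelineError(
            "prep", f"no landmark file at {data_dir / 'landmarks.csv'}"
        )

    try:
        tables = _stage_quantify(cfg, data_dir, out, run_id)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    try:
        vent = _stage_pleth(cfg, data_dir, out, run_id, run_seed)
    except Exception as exc:
        raise PipelineError("pleth", str(exc)) from exc
    try:
        _stage_gas(out, run_id)
    except Exception as exc:
        raise PipelineError("gas", str(exc)) from exc
    try:
        _stage_stats(cfg, tables, vent, out, run_id)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    manifest = {
        "run_id": run_id,
        "seed": run_seed,
        "config": cfg,
        "input_hashes": _file_hashes(data_dir),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
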