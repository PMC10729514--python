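"""Whole-body plethysmography: breath segmentation, ventilation, clustering.

A plethysmography session yields a calibrated respiratory flow trace
(inspiration positive).  Breaths are segmented at upward zero crossings
detected with a Schmitt trigger whose hysteresis band is a fraction of the
robust flow amplitude, so small noise excursions around zero do not split
breaths.  Per breath the module computes inspiratory time, tidal volume
(TV, the time integral of positive flow times the chamber calibration) and
instantaneous rate; per analysis window it reports TV, respiratory rate (RR)
and minute ventilation (MV = TV x RR), conventionally over the final five
minutes of a baseline or challenge period.

Waveform shape analysis resamples each breath to a fixed number of points
(preserving amplitude in mL/s), z-scores per feature and clusters with
k-means, choosing k by maximum mean silhouette.  Category prevalences can be
expressed relative to a reference session (e.g. pre-injury) after matching
categories one-to-one by centroid distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

DEFAULT_MIN_INSP_S = 0.05
DEFAULT_HYSTERESIS_FRAC = 0.1
DEFAULT_WINDOW_S = 300.0
DEFAULT_N_POINTS = 64


@dataclass
class FlowTrace:
    """A sampled respiratory flow signal plus calibration and provenance."""

    flow: np.ndarray  # signal units, inspiration positive
    sample_rate_hz: float
    cal_ml_per_unit: float = 1.0
    condition: str = "baseline"  # or "challenge"
    animal: str = ""
    timepoint: str = "pre"  # pre | d5 | d10

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.flow.size / self.sample_rate_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.flow.size) / self.sample_rate_hz


@dataclass
class Breath:
    """One segmented breath (sample indices into the parent trace)."""

    onset: int
    end_insp: int
    offset: int
    ti_s: float
    tv_ml: float
    rate_bpm: float  # 60 / breath duration

    def __post_init__(self) -> None:
        if not self.onset < self.end_insp <= self.offset:
            raise ValueError(
                f"breath indices must satisfy onset < end_insp <= offset, "
                f"got {self.onset}, {self.end_insp}, {self.offset}"
            )
        if self.tv_ml < 0:
            raise ValueError("tidal volume cannot be negative")


@dataclass
class VentilationSummary:
    """Ventilation metrics over one analysis window."""

    window_s: float
    n_breaths: int
    tv_ml: float  # mean tidal volume per breath
    rr_bpm: float  # breaths per minute
    mv_ml_min: float  # TV x RR
    condition: str = "baseline"


@dataclass
class BreathClusterModel:
    """Partitional clustering of resampled breath waveforms."""

    k: int
    centroids: np.ndarray  # (k, n_points), physical units (mL/s)
    assignments: np.ndarray  # (n_breaths,), int labels in [0, k)
    prevalence: np.ndarray  # (k,), fractions summing to 1
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.prevalence.sum(), 1.0):
            raise ValueError("cluster prevalences must sum to 1")


def segment_breaths(
    trace: FlowTrace,
    min_insp_s: float = DEFAULT_MIN_INSP_S,
    hysteresis_frac: float = DEFAULT_HYSTERESIS_FRAC,
) -> list[Breath]:
    """Delimit breaths at upward zero crossings with hysteresis.

    A Schmitt trigger tracks the flow sign: it switches positive when flow
    exceeds ``+h`` and negative below ``-h``, with ``h = hysteresis_frac``
    times the robust amplitude (95th percentile of |flow|).  Each transition
    to positive opens a breath; the breath runs to the next such transition
    (or the end of the trace).  Tidal volume integrates the positive part of
    the flow over the breath (trapezoidal rule) times the calibration, so it
    is insensitive to the exact trigger sample.  Breaths whose inspiratory
    phase is shorter than ``min_insp_s`` are discarded as artifacts.

    A flat (or sub-hysteresis) trace yields an empty list, not an error.
    """
    if trace.duration_s < 1.0:
        raise ValueError("trace must be at least 1 s long")
    flow = trace.flow
    fs = trace.sample_rate_hz
    amp = float(np.percentile(np.abs(flow), 95))
    if amp == 0.0:
        return []
    h = hysteresis_frac * amp

    # Schmitt trigger state: +1 above +h, -1 below -h, hold otherwise.
    state = np.zeros(flow.size, dtype=np.int8)
    state[flow > h] = 1
    state[flow < -h] = -1
    # forward-fill zeros with the previous decided state
    nz = state != 0
    if not nz.any():
        return []
    idx = np.where(nz, np.arange(flow.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = state[idx]
    first = np.argmax(nz)
    filled[:first] = 0

    onsets = np.where((filled[1:] == 1) & (filled[:-1] != 1))[0] + 1
    if onsets.size == 0:
        return []
    bounds = np.append(onsets, flow.size)

    dt = 1.0 / fs
    breaths: list[Breath] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = flow[a:b]
        # end of inspiration: first downward zero crossing within the breath
        neg = np.where(seg <= 0)[0]
        end_insp = a + int(neg[0]) if neg.size else b - 1
        ti = (end_insp - a) * dt
        if ti < min_insp_s:
            continue
        if end_insp <= a:
            continue
        tv = float(np.trapezoid(np.clip(seg, 0.0, None), dx=dt)) * trace.cal_ml_per_unit
        duration = (b - a) * dt
        breaths.append(
            Breath(
                onset=int(a),
                end_insp=int(end_insp),
                offset=int(b - 1),
                ti_s=ti,
                tv_ml=tv,
                rate_bpm=60.0 / duration,
            )
        )
    return breaths


def ventilation_summary(
    breaths: list[Breath],
    trace: FlowTrace,
    window_s: float = DEFAULT_WINDOW_S,
) -> VentilationSummary | None:
    """TV / RR / MV over the final ``window_s`` seconds of the trace.

    RR is the breath count in the window scaled to breaths/min, TV the mean
    per-breath volume, MV their product.  Returns ``None`` (logged) when the
    window contains no breaths.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    window_s = min(window_s, trace.duration_s)
    start = trace.flow.size - int(round(window_s * trace.sample_rate_hz))
    in_window = [b for b in breaths if b.onset >= start]
    if not in_window:
        logger.warning("no breaths in the final %.0f s window", window_s)
        return None
    tv = float(np.mean([b.tv_ml for b in in_window]))
    rr = len(in_window) * 60.0 / window_s
    return VentilationSummary(
        window_s=window_s,
        n_breaths=len(in_window),
        tv_ml=tv,
        rr_bpm=rr,
        mv_ml_min=tv * rr,
        condition=trace.condition,
    )


def challenge_response(
    baseline: VentilationSummary | None,
    challenge: VentilationSummary | None,
) -> dict[str, float]:
    """Challenge/baseline ratios of TV, RR and MV (NaN where undefined)."""
    if baseline is None or challenge is None:
        raise ValueError("both summaries must be present")
    out = {}
    for name, b, c in [
        ("tv_ratio", baseline.tv_ml, challenge.tv_ml),
        ("rr_ratio", baseline.rr_bpm, challenge.rr_bpm),
        ("mv_ratio", baseline.mv_ml_min, challenge.mv_ml_min),
    ]:
        out[name] = c / b if b > 0 else float("nan")
    return out


def normalize_breaths(
    breaths: list[Breath],
    trace: FlowTrace,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Resample each breath's flow waveform to ``n_points`` samples.

    Linear interpolation over the breath's own duration, so breaths of
    different lengths become comparable rows while amplitude stays in
    physical units (mL/s).  Breaths with fewer than 3 samples are dropped
    (logged).  Returns a (n_retained, n_points) matrix.
    """
    if not breaths:
        raise ValueError("no breaths to normalize")
    cal = trace.cal_ml_per_unit
    rows = []
    dropped = 0
    for b in breaths:
        seg = trace.flow[b.onset : b.offset + 1]
        if seg.size < 3:
            dropped += 1
            continue
        src = np.linspace(0.0, 1.0, seg.size)
        dst = np.linspace(0.0, 1.0, n_points)
        rows.append(np.interp(dst, src, seg) * cal)
    if dropped:
        logger.info("dropped %d degenerate breaths (< 3 samples)", dropped)
    if not rows:
        raise ValueError("all breaths degenerate")
    return np.vstack(rows)


def _zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Z-score per feature (column); zero-variance columns stay centred at 0.

    Per-feature (not per-breath) scaling keeps amplitude differences between
    breath types discriminative.
    """
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    # columns with no real variance (identical breaths up to FP error) are
    # held at zero rather than amplifying rounding noise
    floor = 1e-9 * max(float(np.abs(matrix).max()), 1.0)
    z = np.where(sd > floor, (matrix - mu) / np.where(sd > floor, sd, 1.0), 0.0)
    return z


def cluster_waveforms(
    matrix: np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> BreathClusterModel:
    """Cluster breath waveforms; pick k by maximum mean silhouette.

    K-means on per-feature z-scored rows, for each k in ``k_range``
    (inclusive, truncated so every cluster could hold at least one breath).
    Zero-variance input, or a k_range collapsing to a single k of 1, falls
    back to one category.  Centroids are reported in physical units as the
    mean of the original (unscaled) member rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 breaths to cluster, got {n}")
    lo, hi = int(k_range[0]), int(k_range[1])
    if not 1 <= lo <= hi <= 10:
        raise ValueError(f"k_range must satisfy 1 <= lo <= hi <= 10, got {k_range}")
    hi = min(hi, n - 1)

    z = _zscore_columns(matrix)
    if np.allclose(z, 0.0):  # all breaths identical
        return BreathClusterModel(
            k=1,
            centroids=matrix.mean(axis=0, keepdims=True),
            assignments=np.zeros(n, dtype=int),
            prevalence=np.ones(1),
            silhouette_by_k={},
        )

    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(max(lo, 2), hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(z, labels))
        fits[k] = labels
    if not scores:
        labels = np.zeros(n, dtype=int)
        k_best = 1
    else:
        k_best = max(sorted(scores), key=lambda k: scores[k])
        labels = fits[k_best]

    centroids = np.vstack([matrix[labels == c].mean(axis=0) for c in range(k_best)])
    prevalence = np.bincount(labels, minlength=k_best) / n
    return BreathClusterModel(
        k=k_best,
        centroids=centroids,
        assignments=labels,
        prevalence=prevalence,
        silhouette_by_k=scores,
    )


def match_categories(
    model: BreathClusterModel, reference: BreathClusterModel
) -> dict[int, int]:
    """One-to-one category matching by minimal centroid distance.

    Returns ``{model_label: reference_label}`` via the Hungarian assignment
    on pairwise Euclidean centroid distances.  When the models have unequal
    k, only ``min(k, k_ref)`` pairs are matched; unmatched categories are
    absent from the mapping (and logged).
    """
    d = np.linalg.norm(
        model.centroids[:, None, :] - reference.centroids[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(d)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    for r in range(model.k):
        if r not in mapping:
            logger.warning("model category %d has no reference match", r)
    return mapping


def prevalence_relative(
    model: BreathClusterModel, reference: BreathClusterModel
) -> dict[int, float]:
    """Prevalence of each matched category relative to the reference session.

    Keys are reference category labels; values are
    ``prevalence(model) / prevalence(reference)`` (NaN if the reference
    prevalence is 0).  Unmatched categories are omitted.
    """
    mapping = match_categories(model, reference)
    out: dict[int, float] = {}
    for m_label, r_label in mapping.items():
        p_ref = reference.prevalence[r_label]
        p_mod = model.prevalence[m_label]
        out[r_label] = p_mod / p_ref if p_ref > 0 else float("nan")
    return out
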