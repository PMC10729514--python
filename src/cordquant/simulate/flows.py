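"""Synthetic respiratory flow traces built from four breath archetypes.

Each breath is a half-sine inspiration (positive flow, duration ``ti_s``,
peak ``amplitude_ml_s``) followed by a half-sine expiration whose amplitude
is chosen so the breath integrates to zero net volume.  The four archetypes
mirror the qualitative waveform categories seen in awake rodent
plethysmography: brief low-amplitude sniffs, small and large tidal breaths,
and rare high-amplitude sighs (~2x the large-tidal amplitude).

Default amplitudes/durations give adult-rat-like tidal volumes (~1.5-3 mL)
and rates (~90-100 breaths/min for tidal breathing).  Per-breath amplitude
and timing jitter and additive Gaussian trace noise are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..pleth import FlowTrace


@dataclass(frozen=True)
class ArchetypeSpec:
    """Shape parameters of one breath archetype."""

    amplitude_ml_s: float  # peak inspiratory flow
    ti_s: float  # inspiratory duration
    te_s: float  # expiratory duration

    @property
    def tv_ml(self) -> float:
        """Closed-form inspired volume: integral of A sin(pi t / ti)."""
        return self.amplitude_ml_s * 2.0 * self.ti_s / np.pi


#: Archetype library: sniff (short, low amplitude), small and large tidal
#: breaths, sigh (~2x large-tidal amplitude, long expiration).
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "sniff": ArchetypeSpec(amplitude_ml_s=6.0, ti_s=0.08, te_s=0.10),
    "small_tidal": ArchetypeSpec(amplitude_ml_s=10.0, ti_s=0.25, te_s=0.40),
    "large_tidal": ArchetypeSpec(amplitude_ml_s=16.0, ti_s=0.30, te_s=0.45),
    "sigh": ArchetypeSpec(amplitude_ml_s=32.0, ti_s=0.35, te_s=0.60),
}

#: A plausible awake-baseline mix: mostly small tidal breaths, occasional
#: sniffing bouts, few large breaths, rare sighs.
DEFAULT_MIX: dict[str, float] = {
    "sniff": 0.15,
    "small_tidal": 0.55,
    "large_tidal": 0.25,
    "sigh": 0.05,
}


@dataclass(frozen=True)
class BreathSpec:
    """Parameters of one synthetic plethysmography recording."""

    duration_s: float = 60.0
    sample_rate_hz: float = 1000.0
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    archetypes: dict[str, ArchetypeSpec] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    jitter_amplitude: float = 0.05  # fractional sd of per-breath amplitude
    jitter_duration: float = 0.05  # fractional sd of per-breath ti and te
    noise_sd: float = 0.0  # additive noise, signal units
    cal_ml_per_unit: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.noise_sd < 0 or self.jitter_amplitude < 0 or self.jitter_duration < 0:
            raise ValueError("noise and jitter must be >= 0")
        if not self.mix:
            raise ValueError("archetype mix is empty")
        probs = np.array(list(self.mix.values()), dtype=float)
        if (probs < 0).any():
            raise ValueError("mix prevalences must be >= 0")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"mix prevalences must sum to 1, got {probs.sum()}")
        for name in self.mix:
            if name not in self.archetypes:
                raise ValueError(f"mix references unknown archetype {name!r}")
            a = self.archetypes[name]
            if a.amplitude_ml_s <= 0 or a.ti_s <= 0 or a.te_s <= 0:
                raise ValueError(f"archetype {name!r} must have positive parameters")


@dataclass
class BreathTruth:
    """Ground truth for one generated trace."""

    labels: list[str]  # archetype name per emitted breath
    onsets: np.ndarray  # sample index of each breath onset
    tv_ml: np.ndarray  # true inspired volume per breath
    ti_s: np.ndarray
    te_s: np.ndarray

    def prevalence(self) -> dict[str, float]:
        n = len(self.labels)
        return {a: self.labels.count(a) / n for a in sorted(set(self.labels))}


def _breath_samples(
    amplitude: float, ti: float, te: float, fs: float
) -> np.ndarray:
    n_i = max(int(round(ti * fs)), 2)
    n_e = max(int(round(te * fs)), 2)
    t_i = np.arange(n_i) / fs
    t_e = np.arange(n_e) / fs
    insp = amplitude * np.sin(np.pi * t_i / ti)
    amp_e = amplitude * ti / te  # equal in- and out-volume
    exp = -amp_e * np.sin(np.pi * t_e / te)
    return np.concatenate([insp, exp])


def make_flow_trace(
    spec: BreathSpec,
    *,
    condition: str = "baseline",
    animal: str = "",
    timepoint: str = "pre",
) -> tuple[FlowTrace, BreathTruth]:
    """Generate a flow trace by concatenating archetype breaths.

    Breaths are drawn i.i.d. from the mix; per-breath amplitude and durations
    are jittered multiplicatively; whole breaths are emitted until the next
    one would exceed ``duration_s``.  The per-breath label list aligns 1:1
    with the emitted breaths, and each breath integrates to ~zero net volume
    by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.mix)
    probs = np.array([spec.mix[n] for n in names], dtype=float)
    fs = spec.sample_rate_hz
    max_samples = int(round(spec.duration_s * fs))

    chunks: list[np.ndarray] = []
    labels: list[str] = []
    onsets: list[int] = []
    tvs: list[float] = []
    tis: list[float] = []
    tes: list[float] = []
    total = 0
    while True:
        name = str(rng.choice(names, p=probs))
        a = spec.archetypes[name]
        amp = a.amplitude_ml_s * max(1.0 + spec.jitter_amplitude * rng.standard_normal(), 0.1)
        ti = a.ti_s * max(1.0 + spec.jitter_duration * rng.standard_normal(), 0.2)
        te = a.te_s * max(1.0 + spec.jitter_duration * rng.standard_normal(), 0.2)
        samples = _breath_samples(amp, ti, te, fs)
        if total + samples.size > max_samples and chunks:
            break
        onsets.append(total)
        chunks.append(samples)
        labels.append(name)
        tvs.append(amp * 2.0 * ti / np.pi)
        tis.append(ti)
        tes.append(te)
        total += samples.size
        if total >= max_samples:
            break

    flow = np.concatenate(chunks)
    if spec.noise_sd > 0:
        flow = flow + rng.normal(0.0, spec.noise_sd, size=flow.size)
    # trace is in signal units; the calibration converts to mL/s downstream
    trace = FlowTrace(
        flow=flow / spec.cal_ml_per_unit,
        sample_rate_hz=fs,
        cal_ml_per_unit=spec.cal_ml_per_unit,
        condition=condition,
        animal=animal,
        timepoint=timepoint,
    )
    truth = BreathTruth(
        labels=labels,
        onsets=np.asarray(onsets, dtype=int),
        tv_ml=np.asarray(tvs),
        ti_s=np.asarray(tis),
        te_s=np.asarray(tes),
    )
    return trace, truth


def archetype_matrix(
    spec: BreathSpec,
    n_breaths: int,
    n_points: int = 64,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly sample resampled-breath rows plus integer archetype labels.

    Convenience for clustering benchmarks: rows are single jittered breaths
    resampled to ``n_points`` (as :func:`cordquant.pleth.normalize_breaths`
    would produce), labels index ``sorted(spec.mix)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = sorted(spec.mix)
    probs = np.array([spec.mix[n] for n in names], dtype=float)
    rows = np.empty((n_breaths, n_points))
    labels = np.empty(n_breaths, dtype=int)
    for i in range(n_breaths):
        j = int(rng.choice(len(names), p=probs))
        a = spec.archetypes[names[j]]
        amp = a.amplitude_ml_s * max(1.0 + spec.jitter_amplitude * rng.standard_normal(), 0.1)
        ti = a.ti_s * max(1.0 + spec.jitter_duration * rng.standard_normal(), 0.2)
        te = a.te_s * max(1.0 + spec.jitter_duration * rng.standard_normal(), 0.2)
        samples = _breath_samples(amp, ti, te, spec.sample_rate_hz)
        src = np.linspace(0.0, 1.0, samples.size)
        rows[i] = np.interp(np.linspace(0.0, 1.0, n_points), src, samples)
        labels[i] = j
    return rows, labels
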