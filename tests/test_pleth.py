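"""Breath segmentation, ventilation metrics and waveform clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cordquant.pleth import (
    Breath,
    BreathClusterModel,
    FlowTrace,
    challenge_response,
    cluster_waveforms,
    match_categories,
    normalize_breaths,
    prevalence_relative,
    segment_breaths,
    ventilation_summary,
)
from cordquant.simulate import ArchetypeSpec, BreathSpec, archetype_matrix, make_flow_trace


def sinusoid_trace(a=1.0, f=2.0, duration=60.0, fs=1000.0, noise_sd=0.0, seed=0):
    t = np.arange(0.0, duration, 1.0 / fs)
    flow = a * np.sin(2 * np.pi * f * t)
    if noise_sd:
        flow = flow + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return FlowTrace(flow=flow, sample_rate_hz=fs)


class TestSegmentation:
    def test_zero_flow_yields_no_breaths(self):
        assert segment_breaths(FlowTrace(np.zeros(5000), 1000.0)) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            segment_breaths(FlowTrace(np.zeros(100), 1000.0))

    def test_sinusoid_counts_and_volumes(self):
        """A=1 mL/s at 2 Hz for 60 s: 120 breaths of A/(pi f) each."""
        breaths = segment_breaths(sinusoid_trace())
        assert len(breaths) == 120
        expected_tv = 1.0 / (np.pi * 2.0)
        for b in breaths:
            assert b.tv_ml == pytest.approx(expected_tv, rel=0.005)

    @pytest.mark.parametrize("seed", range(5))
    def test_noise_robust_breath_count(self, seed):
        """2% amplitude noise with 10% hysteresis leaves the count unchanged."""
        breaths = segment_breaths(
            sinusoid_trace(noise_sd=0.02, seed=seed), hysteresis_frac=0.1
        )
        assert len(breaths) == 120

    def test_time_dilation_scaling(self):
        """Slowing the trace 2x halves RR and doubles per-breath volume."""
        fast = segment_breaths(sinusoid_trace(f=2.0))
        slow = segment_breaths(sinusoid_trace(f=1.0))
        assert len(slow) == len(fast) / 2
        tv_fast = np.mean([b.tv_ml for b in fast])
        tv_slow = np.mean([b.tv_ml for b in slow])
        assert tv_slow == pytest.approx(2 * tv_fast, rel=0.005)

    def test_calibration_scales_volume(self):
        tr = sinusoid_trace()
        tr2 = FlowTrace(tr.flow, tr.sample_rate_hz, cal_ml_per_unit=2.5)
        tv1 = segment_breaths(tr)[0].tv_ml
        tv2 = segment_breaths(tr2)[0].tv_ml
        assert tv2 == pytest.approx(2.5 * tv1)

    def test_tv_matches_trapezoid_oracle(self):
        trace, _ = make_flow_trace(BreathSpec(duration_s=20, seed=9, noise_sd=0.0))
        dt = 1.0 / trace.sample_rate_hz
        for b in segment_breaths(trace):
            seg = trace.flow[b.onset : b.offset + 1]
            oracle = np.trapezoid(np.clip(seg, 0, None), dx=dt) * trace.cal_ml_per_unit
            assert b.tv_ml == pytest.approx(oracle, rel=0.005)

    def test_breath_invariants(self):
        trace, _ = make_flow_trace(BreathSpec(duration_s=15, seed=2))
        for b in segment_breaths(trace):
            assert b.onset < b.end_insp <= b.offset
            assert b.tv_ml >= 0


class TestVentilation:
    def test_sixty_second_window_closed_form(self):
        trace = sinusoid_trace()
        s = ventilation_summary(segment_breaths(trace), trace, 60.0)
        assert s.rr_bpm == pytest.approx(120.0)
        assert s.tv_ml == pytest.approx(1.0 / (2 * np.pi), rel=0.005)
        assert s.mv_ml_min == pytest.approx(60.0 / np.pi, rel=0.005)

    def test_single_breath(self):
        b = Breath(onset=0, end_insp=100, offset=400, ti_s=0.1, tv_ml=0.5, rate_bpm=150)
        trace = FlowTrace(np.zeros(30_000), 1000.0)
        s = ventilation_summary([b], trace, 30.0)
        assert s.rr_bpm == pytest.approx(60.0 / 30.0)
        assert s.tv_ml == 0.5

    def test_mv_identity(self):
        trace, _ = make_flow_trace(BreathSpec(duration_s=30, seed=4))
        s = ventilation_summary(segment_breaths(trace), trace, 20.0)
        assert s.mv_ml_min == pytest.approx(s.tv_ml * s.rr_bpm)

    def test_empty_window_returns_none(self, caplog):
        trace = FlowTrace(np.zeros(5000), 1000.0)
        assert ventilation_summary([], trace, 5.0) is None


class TestChallengeResponse:
    def _summary(self, tv, rr):
        from cordquant.pleth import VentilationSummary

        return VentilationSummary(
            window_s=300, n_breaths=int(rr * 5), tv_ml=tv, rr_bpm=rr, mv_ml_min=tv * rr
        )

    def test_identical_summaries(self):
        s = self._summary(0.5, 100)
        assert challenge_response(s, s) == {"tv_ratio": 1.0, "rr_ratio": 1.0, "mv_ratio": 1.0}

    def test_doubled_tidal_volume(self):
        r = challenge_response(self._summary(0.5, 100), self._summary(1.0, 100))
        assert r["tv_ratio"] == 2.0 and r["mv_ratio"] == 2.0 and r["rr_ratio"] == 1.0

    def test_generator_amplitude_recovery(self):
        """A 1.5x challenge amplitude comes back as TV ratio 1.5 at zero noise."""
        base_arch = {"t": ArchetypeSpec(10.0, 0.25, 0.40)}
        chal_arch = {"t": ArchetypeSpec(15.0, 0.25, 0.40)}
        common = dict(
            duration_s=60, mix={"t": 1.0}, jitter_amplitude=0.0, jitter_duration=0.0,
            noise_sd=0.0,
        )
        bl, _ = make_flow_trace(BreathSpec(archetypes=base_arch, **common))
        ch, _ = make_flow_trace(BreathSpec(archetypes=chal_arch, **common))
        sb = ventilation_summary(segment_breaths(bl), bl, 60.0)
        sc = ventilation_summary(segment_breaths(ch), ch, 60.0)
        assert challenge_response(sb, sc)["tv_ratio"] == pytest.approx(1.5, abs=0.05)

    def test_missing_summary_rejected(self):
        with pytest.raises(ValueError):
            challenge_response(None, self._summary(0.5, 100))


class TestNormalize:
    def test_row_count_matches_breaths(self):
        trace, _ = make_flow_trace(BreathSpec(duration_s=20, seed=1))
        breaths = segment_breaths(trace)
        m = normalize_breaths(breaths, trace, 64)
        assert m.shape == (len(breaths), 64)

    def test_identity_when_already_n_points(self):
        flow = np.sin(np.linspace(0, np.pi, 64))
        trace = FlowTrace(np.concatenate([flow, np.zeros(1000)]), 100.0)
        b = Breath(onset=0, end_insp=32, offset=63, ti_s=0.32, tv_ml=1.0, rate_bpm=60)
        row = normalize_breaths([b], trace, 64)[0]
        np.testing.assert_allclose(row, flow, atol=1e-12)

    def test_time_scaled_copy_has_same_shape_row(self):
        t1 = np.linspace(0, 1, 201)
        t2 = np.linspace(0, 1, 401)  # same waveform, twice the duration
        w1, w2 = np.sin(np.pi * t1), np.sin(np.pi * t2)
        trace1 = FlowTrace(np.concatenate([w1, np.zeros(2000)]), 200.0)
        trace2 = FlowTrace(np.concatenate([w2, np.zeros(2000)]), 200.0)
        b1 = Breath(0, 100, 200, 0.5, 1.0, 60)
        b2 = Breath(0, 200, 400, 1.0, 1.0, 30)
        r1 = normalize_breaths([b1], trace1, 64)[0]
        r2 = normalize_breaths([b2], trace2, 64)[0]
        np.testing.assert_allclose(r1, r2, atol=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_breaths([], FlowTrace(np.zeros(2000), 1000.0))


class TestClustering:
    def test_identical_rows_collapse_to_one_category(self):
        m = np.tile(np.sin(np.linspace(0, np.pi, 32)), (20, 1))
        model = cluster_waveforms(m, (2, 5))
        assert model.k == 1
        assert model.prevalence.tolist() == [1.0]

    def test_seed_determinism(self):
        rows, _ = archetype_matrix(BreathSpec(), 200, seed=0)
        a = cluster_waveforms(rows, (2, 6), seed=3)
        b = cluster_waveforms(rows, (2, 6), seed=3)
        assert a.k == b.k
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_permutation_equivariance(self):
        rows, _ = archetype_matrix(
            BreathSpec(jitter_amplitude=0.02, jitter_duration=0.02), 200, seed=0
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(rows.shape[0])
        a = cluster_waveforms(rows, (2, 6), seed=0)
        b = cluster_waveforms(rows[perm], (2, 6), seed=0)
        assert a.k == b.k
        assert adjusted_rand_score(a.assignments[perm], b.assignments) == pytest.approx(1.0)

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError):
            cluster_waveforms(np.zeros((5, 16)), (2, 4))


class TestPrevalence:
    def _model(self, centroids, prevalence):
        prevalence = np.asarray(prevalence, float)
        n = 100
        assignments = np.repeat(
            np.arange(len(prevalence)), (prevalence * n).astype(int)
        )
        return BreathClusterModel(
            k=len(prevalence),
            centroids=np.asarray(centroids, float),
            assignments=assignments,
            prevalence=prevalence,
        )

    def test_identical_distributions_unity_ratios(self):
        c = [[0.0, 0.0], [10.0, 10.0]]
        m = self._model(c, [0.3, 0.7])
        assert prevalence_relative(m, m) == {0: 1.0, 1: 1.0}

    def test_halved_prevalence(self):
        c = [[0.0, 0.0], [10.0, 10.0]]
        ref = self._model(c, [0.2, 0.8])
        mod = self._model(c, [0.1, 0.9])
        ratios = prevalence_relative(mod, ref)
        assert ratios[0] == pytest.approx(0.5)
        assert ratios[1] == pytest.approx(0.9 / 0.8)

    def test_matching_survives_label_shuffle(self):
        ref = self._model([[0.0, 0.0], [10.0, 10.0]], [0.2, 0.8])
        mod = self._model([[10.1, 9.9], [0.1, -0.1]], [0.75, 0.25])
        assert match_categories(mod, ref) == {0: 1, 1: 0}
        ratios = prevalence_relative(mod, ref)
        assert ratios[0] == pytest.approx(0.25 / 0.2)
        assert ratios[1] == pytest.approx(0.75 / 0.8)

    def test_planted_mass_shift_recovered(self):
        """Moving 0.2 of small-tidal mass to large-tidal shows up in the ratios."""
        base_mix = {"sniff": 0.15, "small_tidal": 0.55, "large_tidal": 0.25, "sigh": 0.05}
        shifted = {"sniff": 0.15, "small_tidal": 0.35, "large_tidal": 0.45, "sigh": 0.05}
        kwargs = dict(jitter_amplitude=0.02, jitter_duration=0.02)
        ref_rows, ref_labels = archetype_matrix(
            BreathSpec(mix=base_mix, **kwargs), 1000, seed=0
        )
        mod_rows, mod_labels = archetype_matrix(
            BreathSpec(mix=shifted, **kwargs), 1000, seed=0
        )
        ref_model = cluster_waveforms(ref_rows, (2, 6), seed=0)
        mod_model = cluster_waveforms(mod_rows, (2, 6), seed=0)
        assert ref_model.k == mod_model.k == 4
        ratios = prevalence_relative(mod_model, ref_model)
        # oracle: the realized (sampled) label prevalences of the generator
        names = sorted(base_mix)
        true_ref = np.bincount(ref_labels, minlength=4) / 1000
        true_mod = np.bincount(mod_labels, minlength=4) / 1000
        # match reference cluster labels to archetypes via the reference model
        for r_label, ratio in ratios.items():
            members = ref_labels[ref_model.assignments == r_label]
            arch = np.bincount(members, minlength=4).argmax()
            assert ratio == pytest.approx(true_mod[arch] / true_ref[arch], abs=0.05)
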