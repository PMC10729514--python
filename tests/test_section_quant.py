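"""Histology quantification: thresholds, optical density, counting, vacuoles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordquant.image_prep import flat_field, orient_section, quadrant_masks, side_masks
from cordquant.section_quant import (
    DEFAULT_COUNT_WINDOWS,
    classify_area,
    contralesional_threshold,
    density_profile,
    detect_damage,
    detect_neurons,
    detections_to_frame,
    mirrored_roi,
    neuron_count_table,
    optical_density,
    vacuole_quant,
)
from cordquant.simulate import (
    CellSpec,
    DamageSpec,
    SectionSpec,
    VacuoleSpec,
    disk_mask,
    make_section,
)


class TestThreshold:
    def test_constant_roi(self):
        img = np.full((20, 20), 10.0)
        roi = np.zeros((20, 20), bool)
        roi[2:6, 2:6] = True
        assert contralesional_threshold(img, roi) == 10.0

    def test_mixed_roi_direct_mean_oracle(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 20.0
        roi = np.ones((10, 10), bool)
        assert contralesional_threshold(img, roi) == 10.0

    @given(a=st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=30)
    def test_linearity_in_intensity(self, a):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (16, 16))
        roi = rng.uniform(size=(16, 16)) > 0.5
        t = contralesional_threshold(img, roi)
        assert contralesional_threshold(a * img, roi) == pytest.approx(a * t)

    def test_roi_side_validation(self):
        img = np.zeros((20, 20))
        roi = np.zeros((20, 20), bool)
        roi[5:8, 15:18] = True  # right half
        with pytest.raises(ValueError):
            contralesional_threshold(img, roi, canal_col=10, side_of_lesion="right")
        # fine when the lesion is on the left (ROI is then contralesional)
        contralesional_threshold(img, roi, canal_col=10, side_of_lesion="left")
        with pytest.raises(ValueError):
            contralesional_threshold(img, np.zeros((20, 20), bool))


class TestOpticalDensity:
    def test_small_example(self):
        img = np.array([[10.0, 10.0], [20.0, 20.0]])
        mean, n = optical_density(img, np.ones((2, 2), bool), 10.0)
        assert (mean, n) == (20.0, 2)

    def test_nothing_above_threshold(self):
        img = np.full((4, 4), 5.0)
        mean, n = optical_density(img, np.ones((4, 4), bool), 10.0)
        assert np.isnan(mean) and n == 0

    def test_strictly_above(self):
        img = np.full((4, 4), 10.0)
        mean, n = optical_density(img, np.ones((4, 4), bool), 10.0)
        assert n == 0  # pixels equal to the cutoff do not count

    @given(delta=st.floats(0.01, 50.0))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_under_uniform_raise(self, delta):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (20, 20))
        region = rng.uniform(size=(20, 20)) > 0.4
        thr = 40.0
        base, _ = optical_density(img, region, thr)
        raised, _ = optical_density(img + delta, region, thr)
        assert raised >= base

    def test_planted_double_intensity_recovered(self, mirrored_iba1_section):
        """A 2x ipsilesional intensity effect comes back as OD ratio 2 +/- 0.05."""
        spec, channels, _ = mirrored_iba1_section
        rec = orient_section(channels, spec.canal(), 0.0, "right")
        ff = flat_field(rec.channels["iba1"])
        roi = mirrored_roi(rec.shape, rec.canal_px, rec.side_of_lesion)
        thr = contralesional_threshold(ff, roi)
        sm = side_masks(rec)
        od_ipsi, _ = optical_density(ff, sm["ipsi"], thr)
        od_contra, _ = optical_density(ff, sm["contra"], thr)
        assert od_ipsi / od_contra == pytest.approx(2.0, abs=0.05)


class TestDamage:
    def test_clean_section_gives_empty_mask(self):
        spec = SectionSpec(
            seed=0,
            cells=(
                CellSpec((60, 200), 5, 8000, "neun"),
                CellSpec((200, 60), 5, 8000, "iba1"),
            ),
        )
        channels, _ = make_section(spec)
        assert not detect_damage(channels, 1.0).any()

    def test_planted_damage_recovered(self):
        spec = SectionSpec(
            seed=0,
            cells=(CellSpec((60, 200), 5, 8000, "neun"),),
            damage_regions=(DamageSpec((190, 70), 40, 15000),),
        )
        channels, truth = make_section(spec)
        mask = detect_damage(channels, 1.0)
        coverage = (mask & truth.damage_mask).sum() / truth.damage_mask.sum()
        false_pos = (mask & ~truth.damage_mask).sum() / (~truth.damage_mask).sum()
        assert coverage >= 0.9
        assert false_pos <= 0.05

    def test_detections_inside_mask_flagged_and_not_counted(self):
        img = np.zeros((64, 64))
        img[10:14, 10:14] = 100.0  # 16 px -> excluded-by-size anyway? no: 16 um2 < 23
        img[30:37, 30:37] = 100.0  # 49 px -> small
        exclusion = np.zeros((64, 64), bool)
        exclusion[28:40, 28:40] = True
        quads = np.full((64, 64), 1, np.uint8)
        dets = detect_neurons(img, 50.0, exclusion, quads, 1.0)
        flagged = [d for d in dets if d.excluded_by_damage]
        assert len(flagged) == 1 and flagged[0].size_class == "small"
        # exclusion can only remove counts, never add
        dets_no_excl = detect_neurons(img, 50.0, None, quads, 1.0)
        countable = lambda ds: sum(
            1 for d in ds if d.size_class in ("small", "large") and not d.excluded_by_damage
        )
        assert countable(dets) <= countable(dets_no_excl)


class TestNeurons:
    @pytest.mark.parametrize(
        "radius, expected_class",
        [(5, "small"), (8, "large"), (12, "excluded-by-size")],
    )
    def test_size_classification_by_rasterized_area(self, radius, expected_class):
        spec = SectionSpec(
            image_size_px=(64, 64),
            background_amplitude=0.0,
            background_offset=0.0,
            myelin_intensity=0.0,
            cells=(CellSpec((32, 32), radius, 1000.0, "neun"),),
        )
        channels, truth = make_section(spec)
        quads = np.full((64, 64), 1, np.uint8)
        dets = detect_neurons(channels["neun"], 500.0, None, quads, 1.0)
        assert len(dets) == 1
        assert dets[0].n_pixels == truth.cells[0].n_pixels  # rasterization oracle
        assert dets[0].size_class == expected_class

    def test_size_bins_partition_without_gap(self):
        assert classify_area(22.999) == "excluded-by-size"
        assert classify_area(23.0) == "small"
        assert classify_area(115.999) == "small"
        assert classify_area(116.0) == "large"
        assert classify_area(345.0) == "large"
        assert classify_area(345.001) == "excluded-by-size"

    def test_count_table_bookkeeping(self):
        dets = detections_to_frame([])
        table = neuron_count_table(dets, animals=["r1"])
        assert (table["count"] == 0).all()
        # 3 planted small ipsi-ventral cells at +500 um
        rows = pd.DataFrame(
            {
                "animal": ["r1"] * 3,
                "position_um": [500.0] * 3,
                "quadrant": ["ipsi-ventral"] * 3,
                "size_class": ["small"] * 3,
                "excluded": [False] * 3,
            }
        )
        table = neuron_count_table(rows, windows={"caudal": (0.0, 2000.0)})
        hit = table[
            (table["quadrant"] == "ipsi-ventral") & (table["size_class"] == "small")
        ]
        assert hit["count"].tolist() == [3]
        assert table["count"].sum() == 3

    def test_overlapping_windows_both_count(self):
        rows = pd.DataFrame(
            {
                "animal": ["r1"],
                "position_um": [500.0],
                "quadrant": ["ipsi-ventral"],
                "size_class": ["large"],
                "excluded": [False],
            }
        )
        table = neuron_count_table(rows, windows=DEFAULT_COUNT_WINDOWS)
        by_win = table.groupby("window")["count"].sum()
        assert by_win["caudal"] == 1 and by_win["perilesional"] == 1
        assert by_win["rostral"] == 0


class TestVacuoles:
    def _sides(self, shape):
        rec = orient_section(
            {"neun": np.zeros(shape)},
            ((shape[0] - 1) / 2, (shape[1] - 1) / 2),
            0.0,
            "right",
        )
        return side_masks(rec)

    def test_uniform_myelin_no_holes(self):
        img = np.full((64, 64), 9000.0)
        results = vacuole_quant(img, self._sides((64, 64)))
        assert all(r.n_vacuoles == 0 and r.area_fraction == 0.0 for r in results)

    def test_single_hole_fraction_brute_force(self):
        spec = SectionSpec(
            image_size_px=(64, 64),
            background_amplitude=0.0,
            vacuoles=(VacuoleSpec((32, 48), 4),),
        )
        channels, _ = make_section(spec)
        results = {r.side: r for r in vacuole_quant(channels["myelin"], self._sides((64, 64)))}
        hole_px = int(disk_mask((64, 64), (32, 48), 4).sum())
        ipsi = results["ipsi"]
        assert ipsi.n_vacuoles == 1
        assert ipsi.vacuole_px == hole_px
        assert ipsi.area_fraction == hole_px / ipsi.myelin_px
        assert results["contra"].n_vacuoles == 0

    def test_two_disjoint_holes(self):
        spec = SectionSpec(
            image_size_px=(64, 64),
            vacuoles=(VacuoleSpec((20, 45), 3), VacuoleSpec((45, 50), 4)),
        )
        channels, _ = make_section(spec)
        results = {r.side: r for r in vacuole_quant(channels["myelin"], self._sides((64, 64)))}
        assert results["ipsi"].n_vacuoles == 2

    def test_scale_invariance(self):
        spec = SectionSpec(image_size_px=(64, 64), vacuoles=(VacuoleSpec((32, 48), 4),))
        channels, _ = make_section(spec)
        sides = self._sides((64, 64))
        base = {r.side: r.area_fraction for r in vacuole_quant(channels["myelin"], sides)}
        scaled = {
            r.side: r.area_fraction
            for r in vacuole_quant(3.7 * channels["myelin"], sides)
        }
        assert base == scaled


class TestDensityProfile:
    def test_single_section(self):
        df = pd.DataFrame({"side": ["ipsi"], "position_um": [0.0], "mean_above": [42.0]})
        prof = density_profile(df)
        assert len(prof) == 1
        assert prof.loc[0, "od_mean"] == 42.0

    def test_one_bin_per_section_at_native_spacing(self):
        n = 9
        pos = (np.arange(n) - n // 2) * 140.0
        df = pd.DataFrame(
            {"side": "ipsi", "position_um": pos, "mean_above": np.ones(n)}
        )
        prof = density_profile(df, range_um=10_000, bin_um=140)
        assert len(prof) == n

    def test_exponential_lesion_peaks_at_epicenter(self):
        pos = np.arange(-10, 11) * 140.0
        od = 100.0 * np.exp(-np.abs(pos) / 500.0)
        df = pd.DataFrame({"side": "ipsi", "position_um": pos, "mean_above": od})
        prof = density_profile(df)
        peak_bin = prof.loc[prof["od_mean"].idxmax(), "bin_um"]
        assert abs(peak_bin) <= 140.0

    def test_validation(self):
        df = pd.DataFrame({"side": ["ipsi"], "position_um": [0.0], "mean_above": [1.0]})
        with pytest.raises(ValueError):
            density_profile(df, range_um=0)
        with pytest.raises(ValueError):
            density_profile(df.iloc[:0])
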