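"""Pore measurement, specimen parameters and location summaries."""
import numpy as np
import pytest

from bolipore.core import PoreLabelMap
from bolipore.morphometrics import (
    SpecimenMorphometrics,
    measure_pores,
    specimen_params,
    summarize_location,
)
from bolipore.roi import ROISelection


def _roi(mask, pixel_size=1.0):
    return ROISelection(
        chamber_ranks_included=(1,), mask=mask, area=float(mask.sum() * pixel_size**2)
    )


def _rect_labelmap(shape, rects):
    lab = np.zeros(shape, np.int32)
    for i, (r0, r1, c0, c1) in enumerate(rects, start=1):
        lab[r0:r1, c0:c1] = i
    return PoreLabelMap(lab)


class TestMeasurePores:
    def test_empty_labelmap(self):
        mask = np.ones((64, 64), bool)
        rec = measure_pores(PoreLabelMap(np.zeros((64, 64), np.int32)), _roi(mask), 1.0)
        assert rec.empty

    def test_rectangular_areas_scale_with_pixel_size(self):
        # 40, 60, 80 pixels at 0.5 µm/px -> 10, 15, 20 µm²
        lm = _rect_labelmap((100, 100), [(5, 10, 5, 13), (20, 26, 5, 15), (40, 48, 5, 15)])
        mask = np.ones((100, 100), bool)
        rec = measure_pores(lm, _roi(mask, 0.5), 0.5)
        assert sorted(rec["area_um2"]) == [10.0, 15.0, 20.0]

    def test_centroid_rule_matches_per_pixel_oracle(self):
        """Inclusion is decided by the centroid pixel alone: a pore whose
        body is half inside but centroid outside is excluded, and the
        mirrored case included."""
        lm = _rect_labelmap((100, 100), [(10, 20, 44, 54)])  # centroid col 48.5 -> px 48
        mask = np.zeros((100, 100), bool)
        mask[:, :49] = True  # centroid inside
        rec = measure_pores(lm, _roi(mask), 1.0)
        assert len(rec) == 1 and rec.loc[0, "area_um2"] == 100.0
        mask2 = np.zeros((100, 100), bool)
        mask2[:, :48] = True  # centroid 1 px outside, body half inside
        assert measure_pores(lm, _roi(mask2), 1.0).empty

    def test_misaligned_rasters_rejected(self):
        lm = _rect_labelmap((100, 100), [(10, 20, 10, 20)])
        with pytest.raises(ValueError, match="misaligned"):
            measure_pores(lm, _roi(np.ones((50, 50), bool)), 1.0)

    def test_eccentricity_in_range(self, noisy_specimen):
        img, gt = noisy_specimen
        mask = gt.chamber_map.silhouette()
        rec = measure_pores(gt.pore_mask, _roi(mask), img.pixel_size)
        assert ((rec["eccentricity"] >= 0) & (rec["eccentricity"] < 1)).all()


class TestSpecimenParams:
    def test_forced_arithmetic(self):
        lm = _rect_labelmap((100, 100), [(10, 12, 10, 15)])  # one 10-px pore
        mask = np.zeros((100, 100), bool)
        mask[:50, :20] = True  # 1000 px ROI (window check not applied here)
        rec = measure_pores(lm, _roi(mask), 1.0)
        m = specimen_params(rec, _roi(mask))
        assert m.pore_density == pytest.approx(0.001)
        assert m.mean_pore_size == pytest.approx(10.0)
        assert m.porosity == pytest.approx(1.0)

    def test_zero_pores_flags_mps_undefined(self):
        mask = np.ones((64, 64), bool)
        empty = measure_pores(PoreLabelMap(np.zeros((64, 64), np.int32)), _roi(mask), 1.0)
        with pytest.warns(UserWarning, match="no pores"):
            m = specimen_params(empty, _roi(mask))
        assert m.pore_density == 0.0
        assert m.porosity == 0.0
        assert np.isnan(m.mean_pore_size)

    def test_ground_truth_mask_reproduces_generator_truth(self, noisy_specimen):
        from bolipore.roi import select_roi

        img, gt = noisy_specimen
        roi = select_roi(gt.chamber_map, pixel_size=img.pixel_size)
        m = specimen_params(measure_pores(gt.pore_mask, roi, img.pixel_size), roi)
        truth = gt.true_params["roi"]
        assert m.n_pores == truth["n_pores"]
        assert m.pore_density == pytest.approx(truth["pore_density"], abs=1e-12)
        assert m.mean_pore_size == pytest.approx(truth["mean_pore_size"], abs=1e-9)
        assert m.porosity == pytest.approx(truth["porosity_pct"], abs=1e-9)

    def test_identity_holds_per_specimen_not_for_means(self):
        """porosity == 100·PD·MPS per specimen; the identity fails for
        cohort means of the three parameters."""
        specs = [
            SpecimenMorphometrics("a", "x", "B. spissa", 1000.0, 10, 0.01, 20.0, 20.0),
            SpecimenMorphometrics("b", "x", "B. spissa", 1000.0, 40, 0.04, 5.0, 20.0),
        ]
        for s in specs:
            assert s.porosity == pytest.approx(100 * s.pore_density * s.mean_pore_size)
        mean_pd = np.mean([s.pore_density for s in specs])
        mean_mps = np.mean([s.mean_pore_size for s in specs])
        mean_por = np.mean([s.porosity for s in specs])
        assert mean_por != pytest.approx(100 * mean_pd * mean_mps, rel=1e-3)

    def test_pixel_size_invariance_through_pipeline(self):
        """The same scene measured at 2x resolution gives PD and porosity
        within 2% through segmentation + ROI + measurement."""
        import dataclasses

        from bolipore.roi import select_roi
        from bolipore.segmentation import segment_pores_classical
        from bolipore.synth import SyntheticSpec, generate_specimen

        results = []
        for spec in (
            SyntheticSpec(seed=21),
            dataclasses.replace(SyntheticSpec(seed=21), pixel_size=0.5, image_shape=(1408, 896)),
        ):
            img, gt = generate_specimen(spec)
            lm = segment_pores_classical(img)
            roi = select_roi(gt.chamber_map, pixel_size=img.pixel_size)
            results.append(specimen_params(measure_pores(lm, roi, img.pixel_size), roi))
        a, b = results
        assert a.pore_density == pytest.approx(b.pore_density, rel=0.02)
        assert a.porosity == pytest.approx(b.porosity, rel=0.02)


class TestSummarizeLocation:
    def _spec(self, pd, loc="x"):
        return SpecimenMorphometrics("s", loc, "B. spissa", 60000.0, 1, pd, 10.0, 100 * pd * 10.0)

    def test_forced_arithmetic(self):
        s = summarize_location([self._spec(0.003), self._spec(0.004), self._spec(0.005)])
        row = s.stats.loc["pore_density"]
        assert row["mean"] == pytest.approx(0.004)
        assert row["sd"] == pytest.approx(0.001)
        assert row["sem"] == pytest.approx(0.000577, abs=1e-6)
        assert s.n == 3

    def test_single_specimen_has_no_sd(self):
        s = summarize_location([self._spec(0.004)])
        assert s.stats.loc["pore_density", "mean"] == pytest.approx(0.004)
        assert np.isnan(s.stats.loc["pore_density", "sd"])
        assert np.isnan(s.stats.loc["pore_density", "sem"])

    def test_empty_and_mixed_locations_rejected(self):
        with pytest.raises(ValueError, match="no specimens"):
            summarize_location([])
        with pytest.raises(ValueError, match="multiple locations"):
            summarize_location([self._spec(0.004, "x"), self._spec(0.004, "y")])
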