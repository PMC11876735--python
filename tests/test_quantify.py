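"""Conjugate-view quantification: ROI counting, geometric mean, series building."""

import math

import numpy as np
import pytest

from prrtdose.errors import ConfigurationError
from prrtdose.phantom import render_planar_pair, true_activity
from prrtdose.pipeline import phantom_roiset
from prrtdose.quantify import (
    PlanarScan,
    RoiSet,
    build_time_activity_series,
    conjugate_view_activity,
    roi_counts,
)

from conftest import make_single_organ_spec


def simple_scan(anterior, posterior, **kw):
    defaults = dict(time_post_injection=24.0, duration=60.0, sensitivity=10.0)
    defaults.update(kw)
    return PlanarScan(anterior=anterior, posterior=posterior, **defaults)


def simple_roiset(shape=(20, 20), roi=(0, 10, 0, 10), bg=(12, 20, 0, 20)):
    mask = np.zeros(shape, dtype=bool)
    mask[roi[0]:roi[1], roi[2]:roi[3]] = True
    bgm = np.zeros(shape, dtype=bool)
    bgm[bg[0]:bg[1], bg[2]:bg[3]] = True
    return RoiSet(masks={"organ": mask}, background=bgm, transmission={"organ": 0.25})


class TestRoiCounts:
    def test_mean_background_subtraction(self):
        img = np.zeros((20, 20), dtype=np.int64)
        img[0:10, 0:10] = 100  # ROI sum 10,000 over 100 px
        img[12:20, :] = 10  # background mean 10/px
        scan = simple_scan(img, img)
        cA, cP, floored = roi_counts(scan, simple_roiset(), "organ")
        assert cA == pytest.approx(9000.0) and cP == pytest.approx(9000.0)
        assert not floored

    def test_correction_floors_at_zero_with_flag(self):
        img = np.zeros((20, 20), dtype=np.int64)
        img[0:10, 0:10] = 1
        img[12:20, :] = 50
        scan = simple_scan(img, img)
        with pytest.warns(UserWarning, match="floored"):
            cA, cP, floored = roi_counts(scan, simple_roiset(), "organ")
        assert cA == 0.0 and floored

    def test_matches_brute_force_pixel_loop(self):
        """Vectorized ROI sums equal an explicit per-pixel loop."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            ant = rng.integers(0, 50, size=(20, 20))
            post = rng.integers(0, 50, size=(20, 20))
            roiset = simple_roiset()
            scan = simple_scan(ant, post)
            cA, cP, _ = roi_counts(scan, roiset, "organ")
            for img, got in ((ant, cA), (post, cP)):
                raw = bg_sum = n_bg = 0
                for i in range(20):
                    for j in range(20):
                        if roiset.masks["organ"][i, j]:
                            raw += img[i, j]
                        if roiset.background[i, j]:
                            bg_sum += img[i, j]
                            n_bg += 1
                expected = max(raw - bg_sum / n_bg * roiset.masks["organ"].sum(), 0.0)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_source_rejected(self):
        scan = simple_scan(np.zeros((20, 20), int), np.zeros((20, 20), int))
        with pytest.raises(KeyError):
            roi_counts(scan, simple_roiset(), "nope")


class TestConjugateViewActivity:
    def test_round_number_identity(self):
        scan = simple_scan(np.zeros((2, 2), int), np.zeros((2, 2), int),
                           duration=100.0, sensitivity=10.0)
        # sqrt(8000*2000/0.16) = 10,000 counts; / 1000 counts/MBq = 10 MBq
        assert conjugate_view_activity(8000, 2000, 0.16, scan) == pytest.approx(10.0)

    def test_zero_counts_give_zero_activity(self):
        scan = simple_scan(np.zeros((2, 2), int), np.zeros((2, 2), int))
        assert conjugate_view_activity(0, 0, 0.5, scan) == 0.0

    @pytest.mark.parametrize("transmission", [0.0, -0.1, 1.5])
    def test_invalid_transmission_rejected(self, transmission):
        scan = simple_scan(np.zeros((2, 2), int), np.zeros((2, 2), int))
        with pytest.raises(ValueError, match="transmission"):
            conjugate_view_activity(10, 10, transmission, scan)

    @pytest.mark.parametrize("depth", [0.0, 4.0, 9.16, 15.0])
    def test_noiseless_phantom_recovery_any_depth(self, depth):
        """Recovered activity equals ground truth to 1e-9 at every depth."""
        spec = make_single_organ_spec(depth=depth, amplitudes=(0.4,), rates=(0.01,))
        roiset = phantom_roiset(spec)
        for t in (1.0, 24.0, 168.0):
            ant, post, _ = render_planar_pair(spec, t, 60.0, noise=False)
            scan = simple_scan(ant, post, time_post_injection=t,
                               sensitivity=spec.camera_sensitivity)
            cA, cP, _ = roi_counts(scan, roiset, "organ")
            act = conjugate_view_activity(cA, cP, roiset.transmission["organ"], scan)
            truth = true_activity(spec.organs[0], t, spec.injected_activity)
            assert act == pytest.approx(truth, rel=1e-9)


class TestBuildSeries:
    def _scans(self, spec, times, noise=False):
        out = []
        for t in times:
            ant, post, _ = render_planar_pair(spec, t, 60.0, noise=noise)
            out.append(
                PlanarScan(ant, post, t, 60.0, spec.camera_sensitivity)
            )
        return out

    def test_fraction_is_activity_over_injected(self):
        spec = make_single_organ_spec(amplitudes=(0.01,), rates=(0.001,),
                                      injected_activity=7400.0)
        roiset = phantom_roiset(spec)
        table = build_time_activity_series(
            self._scans(spec, [1.0, 24.0]), roiset, 7400.0
        )
        organ = table[table.source == "organ"]
        truth = [
            true_activity(spec.organs[0], t, 7400.0) / 7400.0
            for t in organ.time_h
        ]
        np.testing.assert_allclose(organ.fraction_ia, truth, rtol=1e-9)

    def test_wholebody_normalization_rescales_all(self):
        spec = make_single_organ_spec(amplitudes=(0.9,), rates=(0.001,))
        roiset = phantom_roiset(spec)
        scans = self._scans(spec, [1.0, 24.0])
        raw = build_time_activity_series(scans, roiset, spec.injected_activity)
        norm = build_time_activity_series(
            scans, roiset, spec.injected_activity, normalize_first_wholebody=True
        )
        first_wb = raw[(raw.source == "whole_body")].fraction_ia.iloc[0]
        np.testing.assert_allclose(
            norm.fraction_ia, raw.fraction_ia / first_wb, rtol=1e-12
        )
        assert norm[(norm.source == "whole_body")].fraction_ia.iloc[0] == pytest.approx(1.0)

    def test_normalization_without_wholebody_roi_rejected(self):
        spec = make_single_organ_spec()
        roiset = phantom_roiset(spec)
        masks = {k: v for k, v in roiset.masks.items() if k != "whole_body"}
        trimmed = RoiSet(masks=masks, background=roiset.background,
                         transmission=roiset.transmission)
        with pytest.raises(ConfigurationError, match="whole_body"):
            build_time_activity_series(
                self._scans(spec, [1.0, 24.0]), trimmed,
                spec.injected_activity, normalize_first_wholebody=True,
            )

    def test_recovered_activity_linear_in_injected(self):
        """Doubling the injected activity doubles the recovered MBq."""
        results = []
        for a0 in (100.0, 200.0):
            spec = make_single_organ_spec(amplitudes=(0.5,), rates=(0.01,),
                                          injected_activity=a0)
            roiset = phantom_roiset(spec)
            table = build_time_activity_series(
                self._scans(spec, [1.0, 24.0]), roiset, a0
            )
            results.append(
                table[table.source == "organ"].fraction_ia.to_numpy() * a0
            )
        np.testing.assert_allclose(results[1], 2 * results[0], rtol=1e-9)

    def test_wholebody_retention_monotone_without_uptake(self):
        spec = make_single_organ_spec(amplitudes=(0.6,), rates=(0.02,),
                                      background_fraction=0.05)
        roiset = phantom_roiset(spec)
        table = build_time_activity_series(
            self._scans(spec, [1.0, 24.0, 48.0, 96.0]), roiset,
            spec.injected_activity,
        )
        wb = table[table.source == "whole_body"].sort_values("time_h")
        assert (np.diff(wb.fraction_ia) < 0).all()


class TestRoiSetValidation:
    def test_overlapping_source_rois_rejected(self):
        m1 = np.zeros((10, 10), bool); m1[0:5, 0:5] = True
        m2 = np.zeros((10, 10), bool); m2[4:8, 4:8] = True
        bg = np.zeros((10, 10), bool); bg[9, :] = True
        with pytest.raises(ValueError, match="overlaps"):
            RoiSet(masks={"a": m1, "b": m2}, background=bg,
                   transmission={"a": 0.5, "b": 0.5})

    def test_background_overlapping_source_rejected(self):
        m1 = np.zeros((10, 10), bool); m1[0:5, 0:5] = True
        bg = np.zeros((10, 10), bool); bg[4:8, :] = True
        with pytest.raises(ValueError, match="background"):
            RoiSet(masks={"a": m1}, background=bg, transmission={"a": 0.5})

    def test_missing_transmission_rejected(self):
        m1 = np.zeros((10, 10), bool); m1[0:5, 0:5] = True
        bg = np.zeros((10, 10), bool); bg[9, :] = True
        with pytest.raises(ConfigurationError, match="transmission"):
            RoiSet(masks={"a": m1}, background=bg, transmission={})
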