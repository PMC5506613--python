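"""Ventilation indices: tidal images, masks, ROIs, GI, spRVD, TIV, ΔEELI."""

import dataclasses
import statistics

import numpy as np
import pytest

from eitsbt.indices import (
    LungMask,
    TidalImage,
    adapted_partition,
    analyze_session,
    analyze_study,
    build_lung_mask,
    delta_eeli,
    gi,
    impedance_ratio,
    regional_ventilation_delay,
    rsbi_eit,
    static_partition,
    tidal_image,
    tiv,
)
from eitsbt.signals import (
    BreathSegmentation,
    GlobalCurve,
    compute_global_curve,
    detect_breaths,
    lowpass_filter,
)
from eitsbt.synthetic import default_phantom_spec, generate_phantom, lung_ellipse_map


def _image(values, mask=None):
    di = np.asarray(values, dtype=float)
    img = TidalImage(di=di, breath_ids=(0,))
    if mask is None:
        mask = di > -np.inf
    return img, LungMask(member=np.asarray(mask, bool), threshold_fraction=0.2)


def gi_brute_force(di, member):
    """Independent evaluation of the inhomogeneity quotient, scalar loops."""
    vals = [float(di[r, c]) for r, c in zip(*np.where(member))]
    med = statistics.median(vals)
    return sum(abs(v - med) for v in vals) / sum(vals)


class TestTidalImage:
    def test_noise_free_phantom_recovers_amplitude_map(self, amp_map):
        # RR 20 at 20 Hz puts the breath extrema exactly on samples, so the
        # tidal image equals the programmed amplitude map to rounding error
        spec = default_phantom_spec(
            lung_amplitude_map=amp_map,
            delay_map=np.zeros_like(amp_map),
            respiratory_rate=20.0,
            noise_sd=0.0,
            cardiac_amplitude=0.0,
        )
        seq, gt = generate_phantom(spec)
        curve = compute_global_curve(seq, gt.lung_mask)
        seg = detect_breaths(curve)
        img = tidal_image(seq, seg)
        np.testing.assert_allclose(
            img.di[gt.lung_mask], amp_map[gt.lung_mask], atol=1e-6
        )

    def test_off_sample_extrema_quantization_is_small(self, quiet_phantom, quiet_spec):
        # at RR 23.5 the extrema fall between samples; the error stays <0.1%
        seq, gt = quiet_phantom
        curve = compute_global_curve(seq, gt.lung_mask)
        seg = detect_breaths(curve)
        img = tidal_image(seq, seg)
        np.testing.assert_allclose(
            img.di[gt.lung_mask], quiet_spec.lung_amplitude_map[gt.lung_mask],
            atol=1e-3,
        )

    def test_constant_movie_gives_zero_image(self):
        from eitsbt.signals import FrameSequence

        seq = FrameSequence(frames=np.full((30, 2, 2), 5.0), sampling_rate=20.0)
        seg = BreathSegmentation(
            breaths=np.array([[0, 10, 20]]), selected=np.array([True])
        )
        assert np.all(tidal_image(seq, seg).di == 0)

    def test_averaging_identical_breaths_is_idempotent(self, amp_map):
        # exact-sampling phantom: every breath has identical frames, so the
        # mean over breaths equals any single-breath image
        spec = default_phantom_spec(
            lung_amplitude_map=amp_map,
            delay_map=np.zeros_like(amp_map),
            respiratory_rate=20.0,
            noise_sd=0.0,
            cardiac_amplitude=0.0,
        )
        seq, gt = generate_phantom(spec)
        curve = compute_global_curve(seq, gt.lung_mask)
        seg = detect_breaths(curve)
        one = BreathSegmentation(
            breaths=seg.breaths, selected=np.eye(1, seg.n_breaths, 1, dtype=bool)[0]
        )
        img_one = tidal_image(seq, one)
        img_all = tidal_image(seq, seg)
        np.testing.assert_allclose(img_one.di, img_all.di, atol=1e-6)


class TestLungMask:
    def test_single_hot_pixel(self):
        di = np.zeros((4, 4))
        di[1, 2] = 10.0
        mask = build_lung_mask([TidalImage(di=di, breath_ids=(0,))], 0.2)
        assert mask.n_pixels == 1 and mask.member[1, 2]

    def test_threshold_boundary_is_inclusive(self):
        di = np.zeros((1, 3))
        di[0] = [10.0, 2.0, 1.9]
        mask = build_lung_mask([TidalImage(di=di, breath_ids=(0,))], 0.2)
        assert mask.member[0, 0] and mask.member[0, 1] and not mask.member[0, 2]

    def test_phantom_mask_matches_programmed_support(self, quiet_phantom):
        seq, gt = quiet_phantom
        curve = compute_global_curve(seq, gt.lung_mask)
        seg = detect_breaths(curve)
        mask = build_lung_mask([tidal_image(seq, seg)], 0.2)
        np.testing.assert_array_equal(mask.member, gt.lung_mask)

    def test_all_zero_images_rejected(self):
        with pytest.raises(ValueError, match="ventilated"):
            build_lung_mask([TidalImage(di=np.zeros((2, 2)), breath_ids=(0,))])


class TestPartitions:
    def _mask_rows(self, first, last, n_rows=32):
        member = np.zeros((n_rows, 4), dtype=bool)
        member[first : last + 1] = True
        return LungMask(member=member, threshold_fraction=0.2)

    def test_sixteen_rows_split_evenly(self):
        part = adapted_partition(self._mask_rows(8, 23))
        assert part.rows == ((8, 12), (12, 16), (16, 20), (20, 24))

    def test_full_extent_matches_static(self):
        part = adapted_partition(self._mask_rows(0, 31))
        assert part.rows == static_partition((32, 32)).rows

    def test_remainder_rows_go_dorsal(self):
        part = adapted_partition(self._mask_rows(10, 19))
        heights = [b - a for a, b in part.rows]
        assert heights == [2, 2, 3, 3]
        assert part.rows[0] == (10, 12) and part.rows[3] == (17, 20)

    def test_narrow_extent_rejected(self):
        with pytest.raises(ValueError, match="4"):
            adapted_partition(self._mask_rows(5, 7))


class TestImpedanceRatio:
    def test_mirror_symmetric_image_gives_unity(self):
        di = np.zeros((8, 4))
        di[1] = 3.0
        di[6] = 3.0  # ventral/dorsal mirror
        img = TidalImage(di=di, breath_ids=(0,))
        assert impedance_ratio(img, static_partition((8, 4))) == pytest.approx(1.0)

    def test_band_sum_arithmetic(self):
        di = np.zeros((4, 1))
        di[:, 0] = [30.0, 20.0, 25.0, 25.0]
        img = TidalImage(di=di, breath_ids=(0,))
        assert impedance_ratio(img, static_partition((4, 1))) == pytest.approx(1.0)

    def test_mirrored_image_is_reciprocal(self):
        rng = np.random.default_rng(3)
        di = rng.uniform(0.1, 5.0, size=(8, 4))
        img = TidalImage(di=di, breath_ids=(0,))
        mirrored = TidalImage(di=di[::-1].copy(), breath_ids=(0,))
        part = static_partition((8, 4))
        assert impedance_ratio(mirrored, part) == pytest.approx(
            1.0 / impedance_ratio(img, part)
        )

    def test_zero_dorsal_sum_rejected(self):
        di = np.zeros((4, 1))
        di[0, 0] = 1.0
        img = TidalImage(di=di, breath_ids=(0,))
        with pytest.raises(ZeroDivisionError, match="IR undefined"):
            impedance_ratio(img, static_partition((4, 1)))


class TestGI:
    def test_hand_computed_example(self):
        img, mask = _image([[1.0, 1.0, 3.0]])
        assert gi(img, mask) == pytest.approx(0.4, abs=1e-12)

    def test_uniform_image_is_zero(self):
        img, mask = _image(np.full((3, 3), 2.5))
        assert gi(img, mask) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        di = rng.uniform(0.1, 4.0, size=(5, 5))
        img, mask = _image(di)
        img2, _ = _image(di * 137.0)
        assert gi(img2, mask) == pytest.approx(gi(img, mask), rel=1e-12)

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            shape = (rng.integers(2, 5), rng.integers(2, 5))
            di = rng.uniform(0.05, 10.0, size=shape)
            member = rng.random(shape) < 0.7
            if member.sum() < 1:
                continue
            img = TidalImage(di=di, breath_ids=(0,))
            mask = LungMask(member=member, threshold_fraction=0.2)
            assert gi(img, mask) == pytest.approx(
                gi_brute_force(di, member), abs=1e-12
            )

    def test_nonpositive_sum_rejected(self):
        img, mask = _image([[0.0, 0.0]])
        with pytest.raises(ValueError, match="GI undefined"):
            gi(img, mask)


class TestTIVAndEELI:
    def _curve_seg(self, trough, peak, n_breaths=12, period=60):
        values = np.full(n_breaths * period + 1, trough, dtype=float)
        breaths = []
        for k in range(n_breaths):
            s, ei, ee = k * period, k * period + period // 2, (k + 1) * period
            values[ei] = peak
            breaths.append((s, ei, ee))
        seg = BreathSegmentation(
            breaths=np.array(breaths), selected=np.ones(n_breaths, bool)
        )
        return GlobalCurve(values=values, sampling_rate=20.0), seg

    def test_baseline_session_is_100_percent(self):
        curve, seg = self._curve_seg(0.0, 2.0)
        au, pct = tiv(curve, seg, baseline_tiv_au=None)
        assert au == pytest.approx(2.0) and pct == 100.0

    def test_percent_of_baseline(self):
        curve, seg = self._curve_seg(0.0, 1.44)
        _, pct = tiv(curve, seg, baseline_tiv_au=2.0)
        assert pct == pytest.approx(72.0)

    def test_nonpositive_swing_rejected(self):
        curve, seg = self._curve_seg(1.0, 1.0)
        with pytest.raises(ValueError, match="invalid breath landmarks"):
            tiv(curve, seg)

    def test_delta_eeli_zero_at_baseline(self):
        curve, seg = self._curve_seg(5.0, 7.0)
        _, pct = delta_eeli(curve, seg, baseline_eeli_au=5.0, baseline_tiv_au=2.0)
        assert pct == 0.0

    def test_delta_eeli_drop_normalized_by_baseline_tiv(self):
        # EELI drop of 1.3 AU against a baseline TIV of 2.0 AU → −65%
        curve, seg = self._curve_seg(3.7, 6.0)
        _, pct = delta_eeli(curve, seg, baseline_eeli_au=5.0, baseline_tiv_au=2.0)
        assert pct == pytest.approx(-65.0)


class TestRSBI:
    @pytest.mark.parametrize(
        "rr,tiv_pct,expected",
        [(23.5, 100.0, 23.5), (26.0, 72.0, 36.1), (18.0, 100.0, 18.0)],
    )
    def test_arithmetic(self, rr, tiv_pct, expected):
        assert rsbi_eit(rr, tiv_pct) == pytest.approx(expected, abs=0.06)

    def test_nonpositive_tiv_rejected(self):
        with pytest.raises(ValueError):
            rsbi_eit(20.0, 0.0)


class TestRegionalVentilationDelay:
    def _delay_phantom(self, delay_map_builder):
        amp = lung_ellipse_map((32, 32))
        delay = delay_map_builder(amp)
        spec = default_phantom_spec(
            lung_amplitude_map=amp,
            delay_map=delay,
            respiratory_rate=15.0,
            inspiration_fraction=0.5,
            duration=60.0,
            noise_sd=0.0,
            cardiac_amplitude=0.0,
        )
        seq, gt = generate_phantom(spec)
        filt = lowpass_filter(seq)
        seg = detect_breaths(compute_global_curve(filt, gt.lung_mask))
        mask = LungMask(member=gt.lung_mask, threshold_fraction=0.2)
        return filt, seg, mask

    def test_zero_delays_give_zero_spread(self):
        filt, seg, mask = self._delay_phantom(lambda amp: np.zeros_like(amp))
        res = regional_ventilation_delay(filt, seg, mask, 40)
        assert res.sd == pytest.approx(0.0, abs=0.5)
        # with no regional delays every pixel crosses the threshold at the
        # waveform's own crossing time: arccos(1−2q)/π of the inspiration
        expected_mean = 100.0 * np.arccos(1 - 2 * 0.40) / np.pi
        assert res.mean == pytest.approx(expected_mean, abs=1.0)
        assert res.n_unreached == 0

    def test_two_group_delay_spread(self):
        def builder(amp):
            delay = np.zeros_like(amp)
            cols = np.arange(amp.shape[1])[None, :] * np.ones(amp.shape[0])[:, None]
            delay[(amp > 0) & (cols >= 16)] = 0.6
            return delay

        filt, seg, mask = self._delay_phantom(builder)
        for thr in (40, 60, 80):
            res = regional_ventilation_delay(filt, seg, mask, thr)
            # half the lung delayed by 0.6 s of a 2.0 s inspiration → SD 15%
            assert res.sd == pytest.approx(15.0, abs=1.0)

    def test_spread_monotonic_in_delay_gap(self):
        sds = []
        for gap in (0.2, 0.4, 0.6, 0.8):
            def builder(amp, gap=gap):
                delay = np.zeros_like(amp)
                cols = np.arange(amp.shape[1])[None, :] * np.ones(amp.shape[0])[:, None]
                delay[(amp > 0) & (cols >= 16)] = gap
                return delay

            filt, seg, mask = self._delay_phantom(builder)
            sds.append(regional_ventilation_delay(filt, seg, mask, 40).sd)
        assert all(b > a for a, b in zip(sds, sds[1:]))


class TestSessionOrchestration:
    def test_baseline_session_reference_values(self, quiet_phantom):
        seq, _ = quiet_phantom
        res = analyze_session(seq)
        assert res.tiv_percent == 100.0
        assert res.delta_eeli_percent == 0.0
        assert res.gi == pytest.approx(0.0, abs=0.5)
        assert res.ir == pytest.approx(1.0, abs=0.01)

    def test_missing_baseline_refs_rejected(self, quiet_phantom):
        seq, _ = quiet_phantom
        t1 = dataclasses.replace(seq, session_label="t1")
        with pytest.raises(ValueError, match="baseline"):
            analyze_session(t1)

    def test_absolute_offset_invariance(self, quiet_phantom):
        seq, _ = quiet_phantom
        shifted = dataclasses.replace(seq, frames=seq.frames + 50.0)
        a = analyze_session(seq)
        b = analyze_session(shifted)
        assert b.tiv_au == pytest.approx(a.tiv_au, rel=1e-9)
        assert b.gi == pytest.approx(a.gi, abs=1e-9)
        assert b.ir == pytest.approx(a.ir, rel=1e-9)
        assert b.rr == pytest.approx(a.rr, rel=1e-12)
        for thr in (40, 60, 80):
            assert b.sp_rvd_sd[thr] == pytest.approx(a.sp_rvd_sd[thr], abs=1e-6)

    def test_study_requires_t0(self, quiet_phantom):
        seq, _ = quiet_phantom
        t1 = dataclasses.replace(seq, session_label="t1")
        with pytest.raises(ValueError, match="t0"):
            analyze_study({"t1": t1})

    def test_study_recovers_ground_truth(self, quiet_spec):
        # noise-free t0/t1 with amplitude factor 0.8: end-to-end recovery
        seq0, gt0 = generate_phantom(quiet_spec)
        spec1 = dataclasses.replace(
            quiet_spec,
            lung_amplitude_map=quiet_spec.lung_amplitude_map * 0.8,
            session_label="t1",
        )
        seq1, _ = generate_phantom(spec1)
        res = analyze_study({"t0": seq0, "t1": seq1})
        assert res.indices["t0"].tiv_au == pytest.approx(gt0.expected_tiv, rel=0.01)
        assert res.indices["t1"].tiv_percent == pytest.approx(80.0, abs=0.5)
        assert res.indices["t1"].delta_eeli_percent == pytest.approx(0.0, abs=1.0)
        np.testing.assert_array_equal(res.mask.member, gt0.lung_mask)
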