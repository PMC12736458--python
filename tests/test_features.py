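"""Hotspot localization, radial profiling and the D-I-R inversion."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thermoseries.bioheat import Environment, HeatSourceParams, recovery_curve, surface_temperature
from thermoseries.features import (
    DEFAULT_RADIUS_M,
    FEATURE_NAMES,
    BoundaryError,
    DegenerateProfileError,
    RadialProfile,
    estimate_depth,
    estimate_intensity,
    estimate_radius,
    frame_descriptors,
    locate_hotspot,
    sample_profile,
    sequence_descriptors,
)
from thermoseries.phantom import CANCER, PhantomConfig, ThermalFrame, generate_sequence

ENV = Environment(te=30.0)


def analytic_profile(q, d, te=30.0, a=DEFAULT_RADIUS_M, env=ENV) -> RadialProfile:
    """Continuous (discretization-free) profile from the closed form."""
    src = HeatSourceParams(q=q, d=d)
    env = Environment(te=te, h0=env.h0, qm=env.qm, at=env.at)
    return RadialProfile(
        center=(0, 0),
        tmax=surface_temperature(0.0, src, env),
        t_a=surface_temperature(a, src, env),
        te=te,
        a=a,
    )


class TestLocateHotspot:
    def test_constant_frame_ties_to_first_masked_pixel(self):
        frame = ThermalFrame(np.full((5, 5), 31.0), 1e-3)
        mask = np.zeros((5, 5), bool)
        mask[2:, 1:] = True
        center, tmax = locate_hotspot(frame, mask)
        assert center == (2, 1)
        assert tmax == 31.0

    def test_two_equal_maxima_row_major_winner(self):
        vals = np.zeros((4, 4))
        vals[1, 3] = vals[2, 0] = 5.0
        center, _ = locate_hotspot(ThermalFrame(vals, 1e-3), np.ones((4, 4), bool))
        assert center == (1, 3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            locate_hotspot(ThermalFrame(np.ones((3, 3)), 1e-3), np.zeros((3, 3), bool))


class TestSampleProfile:
    def _bump_frame(self, n=96, pitch=1e-3, q=0.132, d=0.02):
        c = (n - 1) // 2
        rr, cc = np.indices((n, n))
        r = np.hypot(rr - c, cc - c) * pitch
        src = HeatSourceParams(q=q, d=d)
        vals = ENV.te + src.q / (4 * np.pi * ENV.h0 * (src.d**2 + r**2))
        return ThermalFrame(vals, pitch), np.ones((n, n), bool), (c, c)

    @pytest.mark.parametrize("mode", ["annulus", "line"])
    def test_symmetric_bump_matches_closed_form(self, mode):
        frame, mask, center = self._bump_frame()
        prof = sample_profile(frame, mask, center, mode=mode, te=30.0)
        expected = surface_temperature(
            DEFAULT_RADIUS_M, HeatSourceParams(0.132, 0.02), ENV
        )
        # half-pixel discretization tolerance
        assert prof.t_a == pytest.approx(expected, abs=0.02)

    def test_radius_beyond_mask_reports_achievable_maximum(self):
        frame, mask, center = self._bump_frame(n=16)
        with pytest.raises(BoundaryError) as err:
            sample_profile(frame, mask, center, a=0.5)
        assert err.value.max_radius < 0.5

    def test_default_profiling_radius(self):
        frame, mask, center = self._bump_frame()
        prof = sample_profile(frame, mask, center, te=30.0)
        assert prof.a == 0.0168


class TestInversion:
    def test_exact_algebraic_inverse(self):
        prof = analytic_profile(q=0.132, d=0.02)
        assert estimate_depth(prof) == pytest.approx(0.02, rel=1e-12)
        assert estimate_intensity(prof, ENV) == pytest.approx(0.132, rel=1e-12)

    def test_unit_ratio_gives_depth_equal_to_radius(self):
        prof = RadialProfile((0, 0), tmax=34.0, t_a=32.0, te=30.0, a=0.0168)
        assert estimate_depth(prof) == pytest.approx(0.0168)

    @given(
        q=st.floats(0.01, 1.0),
        d=st.floats(0.005, 0.05),
    )
    def test_round_trip_property(self, q, d):
        prof = analytic_profile(q=q, d=d)
        assert abs(estimate_depth(prof) - d) / d < 1e-9
        assert abs(estimate_intensity(prof, ENV) - q) / q < 1e-9

    def test_radius_form_recovers_effective_depth(self):
        src = HeatSourceParams(q=0.2, d=0.015, r=0.007)
        a = DEFAULT_RADIUS_M
        prof = RadialProfile(
            (0, 0),
            tmax=surface_temperature(0.0, src, ENV, use_radius=True),
            t_a=surface_temperature(a, src, ENV, use_radius=True),
            te=ENV.te,
            a=a,
        )
        assert estimate_depth(prof) == pytest.approx(src.d + src.r, rel=1e-9)

    def test_degenerate_profiles_rejected(self):
        with pytest.raises(DegenerateProfileError):
            estimate_depth(RadialProfile((0, 0), 32.0, 32.0, 30.0, 0.0168))
        with pytest.raises(DegenerateProfileError):
            estimate_depth(RadialProfile((0, 0), 33.0, 30.0, 30.0, 0.0168))

    @pytest.mark.parametrize(
        "q, expected",
        [(0.0, 0.0), (418.6, 1.0), (0.132, 0.0680)],
    )
    def test_radius_estimate(self, q, expected):
        assert estimate_radius(q, ENV) == pytest.approx(expected, abs=1e-3)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            estimate_radius(-0.1, ENV)

    def test_noisy_intensity_median_within_ten_percent(self):
        rng = np.random.default_rng(77)
        q_true, d_true = 0.132, 0.02
        clean = analytic_profile(q=q_true, d=d_true)
        estimates = []
        for _ in range(500):
            noisy = RadialProfile(
                clean.center,
                clean.tmax + rng.normal(0, 0.05),
                clean.t_a + rng.normal(0, 0.05),
                clean.te,
                clean.a,
            )
            try:
                estimates.append(estimate_intensity(noisy, ENV))
            except DegenerateProfileError:
                continue
        assert abs(np.median(estimates) - q_true) / q_true < 0.10


class TestFrameDescriptors:
    def test_constant_frame_is_degenerate(self):
        frame = ThermalFrame(np.full((8, 8), 30.0), 1e-3)
        fv = frame_descriptors(frame, np.ones((8, 8), bool))
        assert fv.tmax == fv.tmean == 30.0
        assert fv.sigma == 0.0
        assert fv.degenerate and math.isnan(fv.q) and math.isnan(fv.d)

    def test_feature_vector_has_five_components(self):
        assert len(FEATURE_NAMES) == 5

    def test_noiseless_phantom_frame_recovers_source(self):
        cfg = PhantomConfig(noise_sd=0.0, q_floor=1.0, seed=0)
        cfg = replace(cfg, cancer=replace(cfg.cancer, heterogeneity_sd=0.0))
        seq = generate_sequence(cfg, CANCER, 1)
        t = float(seq.times[5])
        baseline = recovery_curve(t, cfg.cancer.kinetics)
        fv = frame_descriptors(seq.frame(5), seq.mask, te=baseline)
        src = cfg.cancer.source
        assert fv.d == pytest.approx(src.d, rel=0.02)
        assert fv.q == pytest.approx(src.q, rel=0.02)
        assert fv.tmax == pytest.approx(
            baseline + src.q / (4 * np.pi * cfg.environment.h0 * src.d**2), abs=1e-6
        )

    def test_shift_invariance_with_frame_based_te(self):
        cfg = PhantomConfig(noise_sd=0.0, q_floor=1.0, seed=0)
        cfg = replace(cfg, cancer=replace(cfg.cancer, heterogeneity_sd=0.0))
        seq = generate_sequence(cfg, CANCER, 1)
        frame = seq.frame(5)
        shifted = ThermalFrame(frame.values + 1.5, frame.pitch)
        fv = frame_descriptors(frame, seq.mask)
        fv_shift = frame_descriptors(shifted, seq.mask)
        assert fv_shift.q == pytest.approx(fv.q, rel=1e-9)
        assert fv_shift.d == pytest.approx(fv.d, rel=1e-9)


class TestSequenceDescriptors:
    def test_carry_forward_keeps_length_and_flags(self):
        cfg = PhantomConfig(grid_size=64, noise_sd=0.0, q_floor=1.0, seed=0)
        cfg = replace(cfg, cancer=replace(cfg.cancer, heterogeneity_sd=0.0))
        seq = generate_sequence(cfg, CANCER, 1)
        frames = seq.frames.copy()
        frames[3] = 31.0  # constant frame: inversion degenerate
        seq = replace(seq, frames=frames)
        df = sequence_descriptors(seq)
        assert len(df) == seq.n_frames
        assert df.loc[3, "flag"] == "degenerate"
        assert df.loc[3, "q"] == pytest.approx(df.loc[2, "q"])
        assert not df[["q", "d", "R"]].isna().any().any()

    def test_all_degenerate_fallback(self):
        cfg = PhantomConfig(grid_size=64, noise_sd=0.0, seed=0)
        cfg = replace(cfg, control=replace(cfg.control,
                                           heterogeneity_sd=0.0,
                                           source=replace(cfg.control.source, q=0.0)))
        seq = generate_sequence(cfg, "control", 1)
        df = sequence_descriptors(seq)
        assert (df["flag"] == "all-degenerate").all()
        assert (df["q"] == 0.0).all()

    def test_collapse_depth_to_subject_median(self):
        cfg = PhantomConfig(grid_size=64, seed=0)
        seq = generate_sequence(cfg, CANCER, 1)
        df = sequence_descriptors(seq, collapse_depth=True)
        assert df["d"].nunique() == 1
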