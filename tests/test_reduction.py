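import numpy as np
import pytest

from woodsans import (DetectorFrame, Profile1D, Sector, correct_frame,
                      detect_anisotropy, linear_q_bins, merge_profiles,
                      pixel_q, read_frame, read_profile, reduce_frame,
                      sector_reduce, write_frame, write_profile)
from woodsans.errors import DataError, DomainError, FormatError
from woodsans.reduction import pixel_coordinates


# ---------------------------------------------------------------------------
# pixel_q

class TestPixelQ:
    def test_beam_center(self, short_config):
        assert pixel_q(0.0, short_config) == 0.0

    def test_hand_trigonometry(self, short_config):
        # r=0.1 m, L=1.7 m, lambda=6 A: theta = arctan(0.1/1.7)/2,
        # q = 4 pi sin(theta)/6 = 0.061520...
        assert pixel_q(0.1, short_config) == pytest.approx(0.06152, abs=1e-5)

    def test_small_angle_series(self, short_config):
        # for r/L < 0.05 the small-angle form 2 pi r / (L lambda) holds to 0.2%
        r = np.linspace(0.001, 0.05 * 1.7, 30)
        exact = pixel_q(r, short_config)
        approx = 2 * np.pi * r / (1.7 * 6.0)
        assert np.all(np.abs(exact - approx) / approx < 0.002)

    def test_monotone_in_r(self, short_config):
        r = np.linspace(0.0, 0.5, 100)
        assert np.all(np.diff(pixel_q(r, short_config)) > 0)

    def test_decreasing_in_L_and_lambda(self, short_config, long_config):
        assert pixel_q(0.1, long_config) < pixel_q(0.1, short_config)
        cfg = short_config.__class__(**{**short_config.__dict__, "wavelength_A": 12.0})
        assert pixel_q(0.1, cfg) < pixel_q(0.1, short_config)

    def test_negative_r_rejected(self, short_config):
        with pytest.raises(DomainError):
            pixel_q(-0.01, short_config)


# ---------------------------------------------------------------------------
# correct_frame

class TestCorrectFrame:
    def test_identity_configuration(self, tiny_config):
        counts = np.arange(64 * 64).reshape(64, 64)
        frame = DetectorFrame(counts=counts, monitor_counts=1.0, config=tiny_config)
        I, sigma = correct_frame(frame)
        assert np.array_equal(I, counts)
        assert np.allclose(sigma, np.sqrt(counts))

    def test_hand_arithmetic(self, tiny_config):
        counts = np.full((64, 64), 100)
        frame = DetectorFrame(counts=counts, monitor_counts=1000.0,
                              config=tiny_config,
                              dark=np.full((64, 64), 10.0),
                              sensitivity=np.full((64, 64), 2.0))
        I, _ = correct_frame(frame)
        assert np.allclose(I, 0.045)  # ((100 - 10) / 2) / 1000

    def test_monitor_scaling(self, tiny_config):
        counts = np.random.default_rng(0).poisson(50, (64, 64))
        f1 = DetectorFrame(counts=counts, monitor_counts=100.0, config=tiny_config)
        f2 = DetectorFrame(counts=counts, monitor_counts=200.0, config=tiny_config)
        assert np.allclose(correct_frame(f1)[0], 2.0 * correct_frame(f2)[0])

    def test_shape_mismatch_rejected(self, tiny_config):
        with pytest.raises(FormatError):
            DetectorFrame(counts=np.zeros((32, 32), dtype=int),
                          monitor_counts=1.0, config=tiny_config)
        with pytest.raises(FormatError):
            DetectorFrame(counts=np.zeros((64, 64), dtype=int), monitor_counts=1.0,
                          config=tiny_config, dark=np.zeros((4, 4)))

    def test_nonpositive_sensitivity_rejected(self, tiny_config):
        sens = np.ones((64, 64))
        sens[3, 3] = 0.0
        with pytest.raises(DataError):
            DetectorFrame(counts=np.zeros((64, 64), dtype=int), monitor_counts=1.0,
                          config=tiny_config, sensitivity=sens)


# ---------------------------------------------------------------------------
# anisotropy detection

def _lobed_intensity(config, depth, phi0_deg, base=100.0):
    _, phi, _ = pixel_coordinates(config)
    return base * (1.0 + depth * np.cos(2 * np.radians(phi - phi0_deg)))


class TestDetectAnisotropy:
    def test_uniform_is_isotropic(self, tiny_config):
        I = np.full(tiny_config.detector_shape, 7.0)
        res = detect_anisotropy(I, tiny_config, (0.03, 0.12))
        assert not res.anisotropic
        assert res.score < 0.1

    @pytest.mark.parametrize("phi0", [0.0, 30.0, 117.0])
    def test_lobed_frame_detected_with_orientation(self, tiny_config, phi0):
        I = _lobed_intensity(tiny_config, 0.5, phi0)
        res = detect_anisotropy(I, tiny_config, (0.03, 0.12))
        assert res.anisotropic
        err = abs((res.orientation_deg - phi0 + 90) % 180 - 90)
        assert err < 5.0

    def test_score_scale_invariance(self, tiny_config):
        I = _lobed_intensity(tiny_config, 0.3, 45.0)
        r1 = detect_anisotropy(I, tiny_config, (0.03, 0.12))
        r2 = detect_anisotropy(17.0 * I, tiny_config, (0.03, 0.12))
        assert r1.score == pytest.approx(r2.score, rel=1e-12)

    def test_score_estimates_modulation_depth(self, tiny_config):
        I = _lobed_intensity(tiny_config, 0.5, 0.0)
        res = detect_anisotropy(I, tiny_config, (0.03, 0.12))
        assert res.score == pytest.approx(0.5, abs=0.05)

    def test_empty_annulus_rejected(self, tiny_config):
        I = np.ones(tiny_config.detector_shape)
        with pytest.raises(DataError):
            detect_anisotropy(I, tiny_config, (5.0, 6.0))


# ---------------------------------------------------------------------------
# sector reduction

def brute_force_reduce(intensity, sigma, config, sector, q_bins):
    """Independent per-pixel loop implementation of sector averaging."""
    ny, nx = config.detector_shape
    bx, by = config.beam_center_px
    q_bins = np.asarray(q_bins, dtype=float)
    mids = 0.5 * (q_bins[1:] + q_bins[:-1])
    half0 = (q_bins[1] - q_bins[0]) / 2
    half1 = (q_bins[-1] - q_bins[-2]) / 2
    sums = np.zeros(q_bins.size)
    vars_ = np.zeros(q_bins.size)
    npix = np.zeros(q_bins.size, dtype=int)
    for iy in range(ny):
        for ix in range(nx):
            r = np.hypot(ix - bx, iy - by) * config.pixel_pitch_mm * 1e-3
            theta = 0.5 * np.arctan(r / config.sdd_m)
            q = 4 * np.pi * np.sin(theta) / config.wavelength_A
            if q < q_bins[0] - half0 or q > q_bins[-1] + half1:
                continue
            if sector is not None:
                phi = np.degrees(np.arctan2(iy - by, ix - bx)) % 360.0
                d = abs((phi - sector.center_azimuth_deg + 180) % 360 - 180)
                ok = d <= sector.half_width_deg
                if sector.twofold:
                    ok = ok or abs(d - 180) <= sector.half_width_deg
                if not ok:
                    continue
            b = int(np.searchsorted(mids, q))
            sums[b] += intensity[iy, ix]
            vars_[b] += sigma[iy, ix] ** 2
            npix[b] += 1
    keep = npix > 0
    return (q_bins[keep], sums[keep] / npix[keep],
            np.sqrt(vars_[keep]) / npix[keep], npix)


class TestSectorReduce:
    def test_constant_field(self, tiny_config):
        I = np.full(tiny_config.detector_shape, 4.2)
        sigma = np.zeros_like(I)
        bins = linear_q_bins(tiny_config, 40)
        prof = sector_reduce(I, sigma, tiny_config, None, bins)
        assert np.allclose(prof.I, 4.2, rtol=1e-14)
        assert np.all(prof.sigma_I == 0.0)

    @pytest.mark.parametrize("sector", [
        None,
        Sector(0.0, 25.0, twofold=True),
        Sector(40.0, 30.0, twofold=False),
        Sector(90.0, 25.0, twofold=True),
    ])
    def test_brute_force_oracle(self, tiny_config, rng, sector):
        I = rng.uniform(0.1, 10.0, tiny_config.detector_shape)
        sigma = rng.uniform(0.01, 0.5, tiny_config.detector_shape)
        bins = linear_q_bins(tiny_config, 30)
        prof = sector_reduce(I, sigma, tiny_config, sector, bins)
        q_o, I_o, s_o, _ = brute_force_reduce(I, sigma, tiny_config, sector, bins)
        assert np.allclose(prof.q, q_o, atol=1e-10, rtol=0)
        assert np.allclose(prof.I, I_o, atol=1e-10, rtol=0)
        assert np.allclose(prof.sigma_I, s_o, atol=1e-10, rtol=0)

    def test_count_conservation_across_sector_partition(self, tiny_config, rng):
        # four 45-degree-wide two-fold sectors tile the full circle; centers
        # are chosen so no lattice azimuth falls exactly on a sector boundary
        counts = rng.poisson(100.0, tiny_config.detector_shape).astype(float)
        sigma = np.sqrt(counts)
        bins = linear_q_bins(tiny_config, 30)
        sectors = [Sector(c, 22.5, twofold=True) for c in (10.0, 55.0, 100.0, 145.0)]
        total_pooled = 0.0
        for sec in sectors:
            _, _, _, npix = brute_force_reduce(counts, sigma, tiny_config, sec, bins)
            prof = sector_reduce(counts, sigma, tiny_config, sec, bins)
            # recover pooled counts = mean * n per bin
            n = npix[npix > 0]
            total_pooled += float(np.sum(prof.I * n))
        q, _, _ = pixel_coordinates(tiny_config)
        half0 = (bins[1] - bins[0]) / 2
        in_range = (q >= bins[0] - half0) & (q <= bins[-1] + half0)
        assert total_pooled == pytest.approx(counts[in_range].sum(), rel=1e-9)

    def test_isotropic_frame_sector_agreement(self, tiny_config):
        # Poisson sampling oracle: orthogonal sectors of an isotropic frame
        # agree within propagated errors
        rng = np.random.default_rng(7)
        expected = np.full(tiny_config.detector_shape, 400.0)
        counts = rng.poisson(expected).astype(float)
        sigma = np.sqrt(counts)
        bins = linear_q_bins(tiny_config, 30)
        a = sector_reduce(counts, sigma, tiny_config, Sector(0.0, 25.0), bins,
                          label="aligned")
        m = sector_reduce(counts, sigma, tiny_config, Sector(90.0, 25.0), bins,
                          label="amorphous")
        common = np.intersect1d(a.q, m.q)
        ia = a.I[np.isin(a.q, common)]
        im = m.I[np.isin(m.q, common)]
        sa = a.sigma_I[np.isin(a.q, common)]
        sm = m.sigma_I[np.isin(m.q, common)]
        z2 = ((ia - im) ** 2 / (sa ** 2 + sm ** 2))
        red = z2.mean()
        assert 0.7 < red < 1.3

    def test_empty_sector_rejected(self, tiny_config):
        I = np.ones(tiny_config.detector_shape)
        bins = np.array([0.30, 0.31, 0.32])  # beyond the detector's q reach
        with pytest.raises(DataError):
            sector_reduce(I, np.ones_like(I), tiny_config, None, bins)


# ---------------------------------------------------------------------------
# merging

def _profile(q, I, label="aligned", sigma=None):
    sigma = np.full(len(q), 0.01) if sigma is None else sigma
    return Profile1D(q=np.asarray(q, float), I=np.asarray(I, float),
                     sigma_I=sigma, label=label)


class TestMergeProfiles:
    def test_identical_curves(self):
        q = np.linspace(0.01, 0.1, 20)
        I = 1.0 / q
        merged = merge_profiles(_profile(q, I), _profile(q, I))
        assert merged.provenance["merge_scale"] == pytest.approx(1.0)
        assert np.allclose(merged.q, q)
        assert np.allclose(merged.I, I)

    def test_recovers_scale_factor(self):
        # overlap points shared between the two grids so the noiseless median
        # ratio is exact
        q_long = np.linspace(0.003, 0.04, 38)
        q_short = np.concatenate([q_long[q_long >= 0.02],
                                  np.linspace(0.05, 0.27, 40)])
        f = lambda q: 1e-6 * q ** -3.5 + 0.05
        long = _profile(q_long, f(q_long))
        short = _profile(q_short, 2.0 * f(q_short))
        merged = merge_profiles(long, short)
        assert merged.provenance["merge_scale"] == pytest.approx(0.5, abs=1e-12)

    def test_range_union(self):
        q_long = np.linspace(0.003, 0.04, 40)
        q_short = np.linspace(0.02, 0.27, 60)
        merged = merge_profiles(_profile(q_long, np.ones(40)),
                                _profile(q_short, np.ones(60)))
        assert merged.q.min() == pytest.approx(0.003)
        assert merged.q.max() == pytest.approx(0.27)

    def test_label_mismatch_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        with pytest.raises(DataError):
            merge_profiles(_profile(q, q, "aligned"), _profile(q, q, "amorphous"))

    def test_no_overlap_rejected(self):
        with pytest.raises(DataError):
            merge_profiles(_profile(np.linspace(0.003, 0.01, 5), np.ones(5)),
                           _profile(np.linspace(0.1, 0.2, 5), np.ones(5)))


# ---------------------------------------------------------------------------
# high-level reduction + file formats

class TestReduceFrame:
    def test_isotropic_fallback_single_profile(self, tiny_config, rng):
        counts = rng.poisson(300.0, tiny_config.detector_shape)
        frame = DetectorFrame(counts=counts, monitor_counts=1.0, config=tiny_config)
        profs = reduce_frame(frame)
        assert set(profs) == {"isotropic"}

    def test_anisotropic_two_profiles(self, tiny_config, rng):
        expected = _lobed_intensity(tiny_config, 0.6, 0.0, base=300.0)
        counts = rng.poisson(expected)
        frame = DetectorFrame(counts=counts, monitor_counts=1.0, config=tiny_config)
        profs = reduce_frame(frame)
        assert set(profs) == {"aligned", "amorphous"}


class TestFileFormats:
    def test_frame_round_trip(self, tiny_config, rng, tmp_path):
        counts = rng.poisson(50.0, tiny_config.detector_shape)
        frame = DetectorFrame(counts=counts, monitor_counts=123.0,
                              config=tiny_config, sample_id="UW-CMF-1",
                              sensitivity=np.full(tiny_config.detector_shape, 1.1))
        path = tmp_path / "frame.h5"
        write_frame(path, frame)
        back = read_frame(path)
        assert np.array_equal(back.counts, frame.counts)  # bit-exact integers
        assert back.monitor_counts == frame.monitor_counts
        assert back.sample_id == "UW-CMF-1"
        assert back.config == tiny_config
        assert np.allclose(back.sensitivity, 1.1)
        assert back.dark is None

    def test_profile_round_trip(self, tmp_path):
        q = np.linspace(0.01, 0.2, 25)
        prof = Profile1D(q=q, I=1 / q, sigma_I=0.01 * np.sqrt(1 / q),
                         sigma_q=0.055 * q, label="amorphous",
                         sample_id="42dGt", provenance={"merge_scale": 0.97})
        path = tmp_path / "profile.dat"
        write_profile(path, prof)
        back = read_profile(path)
        assert np.allclose(back.q, prof.q)
        assert np.allclose(back.I, prof.I)
        assert np.allclose(back.sigma_I, prof.sigma_I)
        assert np.allclose(back.sigma_q, prof.sigma_q)
        assert back.label == "amorphous"
        assert back.sample_id == "42dGt"
        assert back.provenance == {"merge_scale": 0.97}
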