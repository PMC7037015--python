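import math

import numpy as np
import pytest

import zsrelax as zr
from zsrelax.sequence import _site_pureshift_modulation

from oracle_dm import oracle_zs_fid


class TestRelaxationFactors:
    @pytest.mark.parametrize(
        "tau,t1,eff,expected",
        [
            (0.0, 1.0, 1.0, -1.0),
            (1000.0, 1.0, 1.0, 1.0),
            (math.log(2.0), 1.0, 1.0, 0.0),
            (0.0625, 4.99, 1.0, -0.97511),
        ],
    )
    def test_ir_factor(self, tau, t1, eff, expected):
        assert zr.ir_recovery_factor(tau, t1, eff) == pytest.approx(expected, abs=1e-5)

    def test_ir_factor_partial_inversion(self):
        # efficiency 0.8: starts at -0.8, still recovers to 1
        assert zr.ir_recovery_factor(0.0, 1.0, 0.8) == pytest.approx(-0.8)

    @pytest.mark.parametrize(
        "delta,t2,expected",
        [(0.0, 1.0, 1.0), (math.log(2.0) * 2.77, 2.77, 0.5), (12.8, 2.77, 0.00984)],
    )
    def test_cpmg_factor(self, delta, t2, expected):
        assert zr.cpmg_decay_factor(delta, t2) == pytest.approx(expected, abs=1e-5)

    def test_invalid_relaxation_times_raise(self):
        with pytest.raises(ValueError):
            zr.ir_recovery_factor(1.0, 0.0)
        with pytest.raises(ValueError):
            zr.cpmg_decay_factor(1.0, -2.0)


class TestConventionalFid:
    def test_single_site_is_damped_sinusoid(self, single_site, homogeneous_field):
        fid = zr.simulate_conventional_fid(single_site, homogeneous_field, 1.0, 0.5, 2000.0)
        t = np.arange(len(fid)) / 2000.0
        spin = single_site.spins[0]
        expected = np.exp((2j * np.pi * 500.0 - 1.0 / spin.t2_s) * t)
        np.testing.assert_allclose(fid, expected, atol=1e-12)

    def test_negative_weight_negates(self, single_site, homogeneous_field):
        f1 = zr.simulate_conventional_fid(single_site, homogeneous_field, 1.0, 0.2, 2000.0)
        f2 = zr.simulate_conventional_fid(single_site, homogeneous_field, -1.0, 0.2, 2000.0)
        np.testing.assert_allclose(f2, -f1, atol=1e-14)

    def test_ax_pair_gives_two_doublets(self, ax_pair, homogeneous_field):
        fid = zr.simulate_conventional_fid(ax_pair, homogeneous_field, 1.0, 2.0, 2000.0)
        spec = zr.fid_to_spectrum(fid, 2000.0, 500.0, zero_fill_factor=4)
        peaks = zr.pick_peaks(spec, min_height_fraction=0.3, measure_width=False)
        assert len(peaks) == 4
        hz = sorted(p.position_ppm * 500.0 for p in peaks)
        assert hz[1] - hz[0] == pytest.approx(7.0, abs=0.1)
        assert hz[3] - hz[2] == pytest.approx(7.0, abs=0.1)

    def test_linearity_in_site_count(self, homogeneous_field):
        s1 = zr.SpinSystem([zr.Spin("A", 1.0, 2.0, 1.0, n_equivalent=1)], [])
        s3 = zr.SpinSystem([zr.Spin("A", 1.0, 2.0, 1.0, n_equivalent=3)], [])
        f1 = zr.simulate_conventional_fid(s1, homogeneous_field, 1.0, 0.2, 2000.0)
        f3 = zr.simulate_conventional_fid(s3, homogeneous_field, 1.0, 0.2, 2000.0)
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-12)

    def test_invalid_duration_raises(self, single_site, homogeneous_field):
        with pytest.raises(ValueError):
            zr.simulate_conventional_fid(single_site, homogeneous_field, 1.0, 0.0, 2000.0)


class TestZSPureShiftFid:
    def test_j_zero_equals_scaled_conventional_singlet(
        self, single_site, homogeneous_field, zs_acq, pulse
    ):
        fid_zs = zr.simulate_zs_pureshift_fid(
            single_site, homogeneous_field, zs_acq, pulse, 1.0
        )
        fid_cv = zr.simulate_conventional_fid(
            single_site, homogeneous_field, 1.0, zs_acq.total_time_s, 2000.0
        )
        frac = zr.slice_geometry(homogeneous_field, pulse, 500.0).fraction
        np.testing.assert_allclose(fid_zs, frac * fid_cv, atol=1e-12)

    def test_j_factor_unity_at_chunk_midpoints(self, ax_pair, zs_acq):
        env = _site_pureshift_modulation(ax_pair, "I", zs_acq)
        sw = zs_acq.spectral_width_hz
        for k in range(zs_acq.n_chunks):
            idx = int(round(k * zs_acq.chunk_duration_s * sw))
            assert env[idx] == pytest.approx(1.0)

    @pytest.mark.parametrize("chunk_ms", [10, 20, 40])
    def test_sideband_spacing_is_inverse_chunk_duration(
        self, ax_pair, homogeneous_field, pulse, chunk_ms
    ):
        chunk = chunk_ms * 1e-3
        zs = zr.ZSAcquisition(
            n_chunks=int(round(0.8 / chunk)), spectral_width_hz=2000.0, chunk_duration_s=chunk
        )
        fid = zr.simulate_zs_pureshift_fid(ax_pair, homogeneous_field, zs, pulse, 1.0)
        spec = zr.fid_to_spectrum(fid, 2000.0, 500.0, zero_fill_factor=4)
        order = np.argsort(spec.axis_hz)
        x = spec.axis_hz[order]
        mag = np.abs(spec.values)[order]
        side = 1.0 / chunk
        for nu in (250.0, 750.0):
            for offset in (-side, side):
                # a genuine local maximum sits within a few grid steps
                window = np.abs(x - (nu + offset)) < 3.0
                assert mag[window].max() > 1e-4 * mag.max()
                i = np.argmax(np.where(window, mag, -np.inf))
                assert mag[i] >= mag[i - 1] and mag[i] >= mag[i + 1]

    def test_sidebands_vanish_without_coupling(self, homogeneous_field, pulse):
        # on-bin frequency, power-of-two record, negligible decay: any
        # residual intensity at +/- 1/chunk_duration is pure chunking artifact
        sys_ = zr.SpinSystem([zr.Spin("A", 1.0, 1e12, 1e12)], [])
        zs = zr.ZSAcquisition(n_chunks=16, spectral_width_hz=2000.0, chunk_duration_s=0.016)
        fid = zr.simulate_zs_pureshift_fid(sys_, homogeneous_field, zs, pulse, 1.0)
        assert len(fid) == 512
        spec = zr.fid_to_spectrum(fid, 2000.0, 500.0, first_point_half=False)
        order = np.argsort(spec.axis_hz)
        x = spec.axis_hz[order]
        mag = np.abs(spec.values)[order]
        side = 1.0 / zs.chunk_duration_s
        for offset in (-side, side):
            mask = np.abs(x - (500.0 + offset)) < 5.0
            assert mag[mask].max() < 1e-9 * mag.max()

    def test_per_element_loss_applied_between_chunks(self, single_site, homogeneous_field, pulse):
        zs = zr.ZSAcquisition(n_chunks=4, spectral_width_hz=2000.0, per_element_loss=0.9)
        zs0 = zr.ZSAcquisition(n_chunks=4, spectral_width_hz=2000.0)
        f_loss = zr.simulate_zs_pureshift_fid(single_site, homogeneous_field, zs, pulse, 1.0)
        f_ideal = zr.simulate_zs_pureshift_fid(single_site, homogeneous_field, zs0, pulse, 1.0)
        ratio = np.abs(f_loss) / np.abs(f_ideal)
        # first half-chunk untouched, later chunks attenuated geometrically
        assert ratio[0] == pytest.approx(1.0)
        assert ratio[-1] == pytest.approx(0.9**4, rel=1e-9)

    def test_slice_outside_sample_warns_and_zeroes(self, pulse):
        # 10 ppm site under a strong gradient: slice at z >> L/2
        sys_ = zr.SpinSystem([zr.Spin("A", 10.0, 1.0, 1.0)], [])
        f = zr.FieldModel(n_z=1, g4_gauss_per_cm=0.56, carrier_ppm=0.0)
        zs = zr.ZSAcquisition(n_chunks=4, spectral_width_hz=8000.0)
        with pytest.warns(UserWarning, match="outside"):
            fid = zr.simulate_zs_pureshift_fid(sys_, f, zs, pulse, 1.0)
        assert np.all(fid == 0)


class TestOracleEquivalence:
    def test_closed_form_matches_density_matrix_propagation(self):
        """AX pair: chunked synthesis vs brute-force quantum propagation."""
        j = 7.0
        sys_ = zr.SpinSystem(
            [zr.Spin("I", 1.0, 1e9, 1e9), zr.Spin("S", 2.0, 1e9, 1e9)],
            [zr.Coupling("I", "S", j)],
            name="ax",
        )
        zs = zr.ZSAcquisition(n_chunks=6, spectral_width_hz=2000.0)
        env = _site_pureshift_modulation(sys_, "I", zs)
        t = np.arange(zs.n_points) / zs.spectral_width_hz
        closed = env * np.exp(2j * np.pi * 500.0 * t)
        oracle = oracle_zs_fid(500.0, 1000.0, j, 6, 0.02, 2000.0)
        assert np.max(np.abs(closed - oracle)) < 1e-6


class TestExperiments:
    def test_ir_series_follows_recovery_factor(self, single_site, homogeneous_field):
        scheme = zr.IRScheme([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        series = zr.run_ir_experiment(
            single_site, homogeneous_field, scheme, mode="conventional",
            duration=0.2, spectral_width=2000.0,
        )
        assert len(series.delays) == 10
        base = zr.simulate_conventional_fid(single_site, homogeneous_field, 1.0, 0.2, 2000.0)
        for tau, fid in zip(scheme.tau1_list, series.fids):
            w = zr.ir_recovery_factor(tau, single_site.spins[0].t1_s)
            np.testing.assert_allclose(fid, w * base, atol=1e-12)

    def test_ir_saturation_limit(self, single_site, homogeneous_field):
        scheme = zr.IRScheme([50.0, 100.0, 200.0])  # all >> T1 = 2 s
        series = zr.run_ir_experiment(
            single_site, homogeneous_field, scheme, mode="conventional",
            duration=0.1, spectral_width=2000.0,
        )
        ref = series.fids[-1]
        for fid in series.fids:
            assert np.max(np.abs(fid - ref)) <= 1e-6 * np.max(np.abs(ref))

    def test_empty_delay_list_rejected(self):
        with pytest.raises(ValueError):
            zr.IRScheme([])
        with pytest.raises(ValueError):
            zr.CPMGScheme([])

    def test_cpmg_delta_must_be_multiple_of_tau2(self):
        with pytest.raises(ValueError, match="multiple"):
            zr.CPMGScheme([0.0251], tau2_s=200e-6)

    def test_cpmg_peak_amplitudes_decay_monotonically(self, single_site, homogeneous_field):
        scheme = zr.CPMGScheme([0.1, 0.4, 1.6, 6.4], tau2_s=200e-6)
        series = zr.run_cpmg_experiment(
            single_site, homogeneous_field, scheme, mode="conventional",
            duration=0.2, spectral_width=2000.0,
        )
        amps = [np.abs(fid).max() for fid in series.fids]
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_zs_mode_requires_acquisition(self, single_site, homogeneous_field):
        with pytest.raises(ValueError):
            zr.run_ir_experiment(single_site, homogeneous_field, zr.IRScheme([1.0]), mode="zs")

    def test_chunk_bookkeeping_total_time(self):
        assert zr.ZSAcquisition(40, 2000.0, 0.02).total_time_s == pytest.approx(0.8)
        assert zr.ZSAcquisition(30, 4000.0, 0.02).total_time_s == pytest.approx(0.6)
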