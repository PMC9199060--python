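import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusbeam import (
    ArrayGeometry,
    PulseSpec,
    ScattererPhantom,
    TxEvent,
    focus_delays,
    make_phantom,
    make_tone_burst,
    measure_beam_metrics,
    planewave_delays,
    simulate_incident_intensity,
    synthesize_channel_data,
)
from conftest import direct_rf_oracle, focused_tx


class TestToneBurst:
    def test_160_cycles_at_20mhz_is_640_samples(self):
        wave = make_tone_burst(PulseSpec(5e6, 160, "therapy"), 20e6)
        assert wave.size == 640

    def test_2_cycles_at_20mhz_is_8_samples(self):
        assert make_tone_burst(PulseSpec(5e6, 2), 20e6).size == 8

    def test_undersampled_fs_rejected_naming_constraint(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_tone_burst(PulseSpec(5e6, 2), 15e6)

    def test_peak_amplitude_is_one(self):
        for fs in (20e6, 25e6, 31e6):
            wave = make_tone_burst(PulseSpec(5e6, 4), fs)
            assert np.max(np.abs(wave)) == pytest.approx(1.0)

    def test_hann_taper_flag(self):
        rect = make_tone_burst(PulseSpec(5e6, 8), 40e6)
        hann = make_tone_burst(PulseSpec(5e6, 8), 40e6, taper="hann")
        assert hann.size == rect.size
        # tapered burst is suppressed at the ends relative to the middle
        assert np.abs(hann[:4]).max() < 0.2 * np.abs(hann).max()

    def test_pulse_spec_validation(self):
        with pytest.raises(ValueError):
            PulseSpec(5e6, 0)
        with pytest.raises(ValueError):
            PulseSpec(-1.0, 2)
        with pytest.raises(ValueError):
            PulseSpec(5e6, 2, "bogus")


class TestDelays:
    def test_on_axis_focus_symmetric_edge_zero(self, geom_mid):
        d = focus_delays(geom_mid, (0.0, 30e-3))
        assert d[0] == pytest.approx(0.0, abs=1e-15)
        assert d[-1] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(d, d[::-1], atol=1e-15)
        assert d[geom_mid.n_elements // 2] > 0

    def test_plane_wave_limit_deep_focus(self, geom_mid):
        d = focus_delays(geom_mid, (0.0, 100e3))  # 100 km
        assert np.max(d) < 1e-12

    def test_three_element_hand_geometry(self):
        geom = ArrayGeometry(n_elements=3, pitch=0.3e-3)
        d = focus_delays(geom, (0.0, 10e-3))
        expected = (np.hypot(10e-3, 0.3e-3) - 10e-3) / geom.c
        assert d[1] == pytest.approx(expected, rel=1e-12)
        assert d[0] == d[2] == 0.0

    def test_nonpositive_focal_depth_rejected(self, geom_mid):
        with pytest.raises(ValueError):
            focus_delays(geom_mid, (0.0, 0.0))

    def test_planewave_zero_angle_all_zero(self, geom_mid):
        np.testing.assert_array_equal(planewave_delays(geom_mid, 0.0), 0.0)

    def test_planewave_linear_max_at_edge(self, geom_full):
        d = planewave_delays(geom_full, 18.0)
        steps = np.diff(d)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)
        assert d.argmax() == geom_full.n_elements - 1
        assert d.min() == 0.0

    def test_planewave_negative_angle_mirrors(self, geom_full):
        d_pos = planewave_delays(geom_full, 18.0)
        d_neg = planewave_delays(geom_full, -18.0)
        np.testing.assert_allclose(d_neg, d_pos[::-1], rtol=1e-12)

    def test_planewave_angle_limit(self, geom_mid):
        with pytest.raises(ValueError):
            planewave_delays(geom_mid, 90.0)


class TestSynthesizeChannelData:
    def test_single_scatterer_single_element_single_path(self):
        geom = ArrayGeometry(n_elements=3, pitch=0.3e-3)
        r = 10e-3
        ph = ScattererPhantom([[0.0, r]], [2.0])
        tx = TxEvent(delays=np.zeros(3), kind="plane", angle_deg=0.0)
        wave = make_tone_burst(PulseSpec(5e6, 2), geom.fs)
        active = np.array([False, True, False])
        chan = synthesize_channel_data(ph, geom, tx, wave, active_tx=active)
        # replica on the center element starts at sample 2r/c * fs
        start = 2 * r / geom.c * geom.fs
        trace = chan.rf[1]
        first = np.flatnonzero(np.abs(trace) > 1e-6 * np.abs(trace).max())[0]
        assert abs(first - start) <= 1.5
        # amplitude: a / r^2 spreading over the round trip; the sampled peak
        # sits below the continuous one at four samples per cycle
        assert 0.6 * 2.0 / r**2 < np.abs(trace).max() <= 1.02 * 2.0 / r**2

    def test_zero_amplitude_phantom_gives_zero_rf(self, geom_small, vis_wave):
        ph = ScattererPhantom([[0.0, 10e-3], [1e-3, 12e-3]], [0.0, 0.0])
        tx = focused_tx(geom_small, (0.0, 10e-3))
        chan = synthesize_channel_data(ph, geom_small, tx, vis_wave)
        assert np.all(chan.rf == 0.0)

    def test_symmetric_scatterers_give_element_reversed_rf(self, geom_small, vis_wave):
        ph = ScattererPhantom([[1.5e-3, 9e-3], [-1.5e-3, 9e-3]], [1.0, 1.0])
        tx = focused_tx(geom_small, (0.0, 9e-3))
        chan = synthesize_channel_data(ph, geom_small, tx, vis_wave)
        np.testing.assert_allclose(chan.rf, chan.rf[::-1], rtol=1e-9, atol=1e-9)

    def test_matches_direct_path_oracle(self, geom_small, vis_wave):
        rng = np.random.default_rng(0)
        ph = ScattererPhantom(
            np.column_stack([rng.uniform(-3e-3, 3e-3, 12),
                             rng.uniform(5e-3, 15e-3, 12)]),
            rng.rayleigh(1.0, 12),
        )
        tx = focused_tx(geom_small, (1e-3, 10e-3))
        chan = synthesize_channel_data(ph, geom_small, tx, vis_wave)
        oracle = direct_rf_oracle(ph, geom_small, tx, vis_wave, chan.n_samples)
        err = np.abs(chan.rf - oracle).max() / np.abs(oracle).max()
        assert err < 0.015  # fine-lattice resampling residual at oversample=8

    def test_oversampling_converges_to_oracle(self, geom_small, vis_wave):
        ph = ScattererPhantom([[0.7e-3, 8e-3], [-1.1e-3, 11e-3]], [1.0, 0.5])
        tx = focused_tx(geom_small, (0.0, 9e-3))
        errs = []
        for q in (2, 8):
            chan = synthesize_channel_data(ph, geom_small, tx, vis_wave, oversample=q)
            oracle = direct_rf_oracle(ph, geom_small, tx, vis_wave, chan.n_samples)
            errs.append(np.abs(chan.rf - oracle).max() / np.abs(oracle).max())
        assert errs[1] < 0.5 * errs[0]

    def test_linearity_in_phantoms(self, geom_small, vis_wave):
        tx = focused_tx(geom_small, (0.0, 10e-3))
        a = ScattererPhantom([[1e-3, 8e-3]], [1.0])
        b = ScattererPhantom([[-2e-3, 12e-3]], [0.7])
        n = 600
        rf_a = synthesize_channel_data(a, geom_small, tx, vis_wave, n_samples=n).rf
        rf_b = synthesize_channel_data(b, geom_small, tx, vis_wave, n_samples=n).rf
        rf_ab = synthesize_channel_data(a + b, geom_small, tx, vis_wave, n_samples=n).rf
        np.testing.assert_allclose(rf_ab, rf_a + rf_b, atol=1e-9 * np.abs(rf_ab).max())

    def test_reciprocity_swapping_tx_and_rx_elements(self, geom_small, vis_wave):
        """A single-element transmit received on element j arrives at the
        same time as the swapped pair."""
        ph = ScattererPhantom([[0.9e-3, 9e-3]], [1.0])
        tx_zero = np.zeros(geom_small.n_elements)
        out = {}
        for i, j in ((2, 11), (11, 2)):
            active = np.zeros(geom_small.n_elements, dtype=bool)
            active[i] = True
            chan = synthesize_channel_data(
                ph, geom_small, TxEvent(delays=tx_zero, kind="plane", angle_deg=0.0),
                vis_wave, active_tx=active, n_samples=500,
            )
            out[(i, j)] = chan.rf[j]
        np.testing.assert_allclose(out[(2, 11)], out[(11, 2)], rtol=1e-9, atol=1e-12)

    def test_seeded_noise_is_deterministic(self, geom_small, vis_wave):
        ph = ScattererPhantom([[0.0, 10e-3]], [1.0])
        tx = focused_tx(geom_small, (0.0, 10e-3))
        rf1 = synthesize_channel_data(ph, geom_small, tx, vis_wave,
                                      noise_sd=0.1, rng_seed=7).rf
        rf2 = synthesize_channel_data(ph, geom_small, tx, vis_wave,
                                      noise_sd=0.1, rng_seed=7).rf
        np.testing.assert_array_equal(rf1, rf2)

    def test_scatterer_behind_array_rejected(self):
        with pytest.raises(ValueError):
            ScattererPhantom([[0.0, -1e-3]], [1.0])

    def test_empty_waveform_rejected(self, geom_small):
        ph = ScattererPhantom([[0.0, 10e-3]], [1.0])
        tx = focused_tx(geom_small, (0.0, 10e-3))
        with pytest.raises(ValueError):
            synthesize_channel_data(ph, geom_small, tx, np.array([]))


class TestIncidentIntensity:
    def test_single_element_field_radially_symmetric(self):
        geom = ArrayGeometry(n_elements=1, pitch=0.3e-3)
        wave = make_tone_burst(PulseSpec(5e6, 4), geom.fs)
        tx = TxEvent(delays=np.zeros(1), kind="plane", angle_deg=0.0)
        r = 8e-3
        th = np.linspace(-0.9, 0.9, 7)
        vals = [
            simulate_incident_intensity(
                geom, tx, wave, np.array([r * np.sin(t)]), np.array([r * np.cos(t)])
            )[0, 0]
            for t in th
        ]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-9)

    def test_focused_long_burst_peaks_near_focus(self, geom_mid):
        focus = (0.0, 25e-3)
        tx = focused_tx(geom_mid, focus)
        wfs = 8 * geom_mid.fs
        wave = make_tone_burst(PulseSpec(5e6, 40, "therapy"), wfs)
        gx = np.linspace(-2e-3, 2e-3, 41)
        gz = np.linspace(20e-3, 30e-3, 51)
        field = simulate_incident_intensity(geom_mid, tx, wave, gx, gz,
                                            waveform_fs=wfs)
        iz, ix = np.unravel_index(field.argmax(), field.shape)
        lam = geom_mid.wavelength
        assert abs(gx[ix] - focus[0]) <= lam
        assert abs(gz[iz] - focus[1]) <= 2 * lam  # slight proximal focal shift

    def test_grid_behind_array_rejected(self, geom_small, vis_wave):
        tx = focused_tx(geom_small, (0.0, 10e-3))
        with pytest.raises(ValueError):
            simulate_incident_intensity(geom_small, tx, vis_wave,
                                        np.array([0.0]), np.array([-1e-3]))


class TestBeamMetrics:
    @staticmethod
    def _gaussian_field(sx, sz):
        x = np.linspace(-3e-3, 3e-3, 301)
        z = np.linspace(27e-3, 33e-3, 301)
        xx, zz = np.meshgrid(x, z)
        f = np.exp(-(xx**2) / (2 * sx**2) - ((zz - 30e-3) ** 2) / (2 * sz**2))
        return f, x, z

    def test_gaussian_fwhm_closed_form(self):
        sx, sz = 0.4e-3, 1.1e-3
        f, x, z = self._gaussian_field(sx, sz)
        m = measure_beam_metrics(f, x, z, (0.0, 30e-3))
        assert m.beamwidth == pytest.approx(2 * sx * np.sqrt(2 * np.log(2)), abs=x[1] - x[0])
        assert m.dof == pytest.approx(2 * sz * np.sqrt(2 * np.log(2)), abs=z[1] - z[0])

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        f, x, z = self._gaussian_field(0.5e-3, 1.0e-3)
        m1 = measure_beam_metrics(f, x, z, (0.0, 30e-3))
        m2 = measure_beam_metrics(scale * f, x, z, (0.0, 30e-3))
        assert m1.beamwidth == pytest.approx(m2.beamwidth)
        assert m1.dof == pytest.approx(m2.dof)

    def test_off_peak_focus_warns_but_computes(self):
        f, x, z = self._gaussian_field(0.5e-3, 1.0e-3)
        with pytest.warns(RuntimeWarning, match="not a local maximum"):
            m = measure_beam_metrics(f, x, z, (0.8e-3, 30e-3))
        assert m.beamwidth >= 0.0

    def test_focus_outside_grid_rejected(self):
        f, x, z = self._gaussian_field(0.5e-3, 1.0e-3)
        with pytest.raises(ValueError):
            measure_beam_metrics(f, x, z, (10e-3, 30e-3))


class TestMakePhantom:
    def test_two_region_ratio_by_construction(self):
        ph = make_phantom(
            "two_region",
            dict(xlim=(-5e-3, 5e-3), zlim=(20e-3, 30e-3), x_split=0.0,
                 n_scatterers=2000, ratio=2.0),
            rng_seed=3,
        )
        left = ph.positions[:, 0] < 0.0
        ratio = ph.amplitudes[left].mean() / ph.amplitudes[~left].mean()
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_points_phantom_exact_listing(self):
        ph = make_phantom("points", dict(positions=[(0.0, 30e-3)]))
        assert ph.n_scatterers == 1
        np.testing.assert_array_equal(ph.positions, [[0.0, 30e-3]])

    def test_speckle_deterministic_under_seed(self):
        params = dict(xlim=(-5e-3, 5e-3), zlim=(20e-3, 30e-3), n_scatterers=500)
        a = make_phantom("speckle", params, rng_seed=11)
        b = make_phantom("speckle", params, rng_seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)

    def test_balloon_disk_outside_gap_rejected(self):
        with pytest.raises(ValueError, match="outside the anechoic gap"):
            make_phantom(
                "balloon",
                dict(xlim=(-5e-3, 5e-3), gap_zlim=(10e-3, 20e-3),
                     background_zlim=(20e-3, 30e-3), center=(0.0, 19e-3),
                     radius=3e-3, n_background=10, n_disk=10),
            )

    def test_balloon_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            make_phantom(
                "balloon",
                dict(xlim=(-5e-3, 5e-3), gap_zlim=(10e-3, 22e-3),
                     background_zlim=(20e-3, 30e-3), center=(0.0, 15e-3),
                     radius=3e-3, n_background=10, n_disk=10),
            )

    def test_balloon_geometry(self):
        ph = make_phantom(
            "balloon",
            dict(xlim=(-8e-3, 8e-3), gap_zlim=(5e-3, 25e-3),
                 background_zlim=(25e-3, 40e-3), center=(0.0, 15e-3),
                 radius=4e-3, n_background=300, n_disk=200, amp_scale=10.0),
            rng_seed=1,
        )
        z = ph.positions[:, 1]
        in_disk = np.hypot(ph.positions[:, 0], z - 15e-3) <= 4e-3 + 1e-12
        in_gap_not_disk = (z >= 5e-3) & (z <= 25e-3) & ~in_disk
        assert not np.any(in_gap_not_disk)
        assert in_disk.sum() == 200
        assert ph.amplitudes[in_disk].mean() > 5 * ph.amplitudes[~in_disk].mean()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("bogus", {})

    def test_text_round_trip(self, tmp_path):
        ph = make_phantom("speckle", dict(xlim=(-1e-3, 1e-3), zlim=(5e-3, 6e-3),
                                          n_scatterers=40), rng_seed=5)
        path = tmp_path / "phantom.txt"
        ph.to_text(path)
        back = ScattererPhantom.from_text(path)
        assert back.label == "speckle"
        np.testing.assert_allclose(back.positions, ph.positions, rtol=1e-8)
        np.testing.assert_allclose(back.amplitudes, ph.amplitudes, rtol=1e-8)


class TestGeometryValidation:
    def test_fs_below_four_samples_per_wavelength_rejected(self):
        with pytest.raises(ValueError, match="four samples"):
            ArrayGeometry(fs=15e6)

    def test_element_positions_centered(self, geom_full):
        x = geom_full.element_x
        assert x[0] == pytest.approx(-x[-1])
        assert np.all(np.diff(x) > 0)
        assert geom_full.aperture_width == pytest.approx(38.1e-3)
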