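"""Pulsatile ground truth, photon-table replay, correlation evaluation and
crossing-point location."""

import numpy as np
import pytest

from dcsmc.forward import (
    FlowAbsorptionState,
    IRFKernel,
    LagGrid,
    ToFGrid,
    convolve_irf,
    g1_surface,
)
from dcsmc.medium import adult_head_preset
from dcsmc.pulsatile import (
    CrossingResult,
    CWConfig,
    SCOSConfig,
    TDConfig,
    WaveformSpec,
    cardiac_pulse,
    depth_sweep,
    evaluate_recovery,
    find_crossing,
    make_waveform,
    simulate_timeseries,
    triangular_pulse,
)


@pytest.fixture(scope="module")
def default_series():
    return make_waveform(WaveformSpec(), adult_head_preset())


class TestWaveform:
    def test_pulsatility_index_realized(self, default_series):
        for col in (0, 3):  # scalp, brain
            a = default_series.alpha_db[:, col]
            pi = (a.max() - a.min()) / a.mean()
            assert pi == pytest.approx(0.8, rel=0.01)

    def test_zero_pulsatility_is_constant(self):
        s = make_waveform(
            WaveformSpec(pulsatility_index=0.0), adult_head_preset()
        )
        assert np.ptp(s.alpha_db, axis=0).max() == 0.0
        np.testing.assert_array_equal(s.rcbf, 0.0)

    def test_reference_waveforms_zero_at_start(self, default_series):
        assert default_series.rcbf[0] == 0.0
        assert default_series.rsbf[0] == 0.0

    def test_scalp_delayed_by_phase_shift(self, default_series):
        """π/4 of a 1 Hz beat ⇒ scalp lags brain by 0.125 s (circular
        cross-correlation peak)."""
        s = default_series
        b = s.alpha_db[:, 3] - s.alpha_db[:, 3].mean()
        sc = s.alpha_db[:, 0] - s.alpha_db[:, 0].mean()
        shifts = np.arange(len(b))
        cc = [np.dot(b, np.roll(sc, -k)) for k in shifts]
        best = shifts[int(np.argmax(cc))]
        lag_s = best / s.spec.fs
        expected = (np.pi / 4) / (2 * np.pi * 1.0)
        # waveform is periodic at 1 Hz: compare modulo the beat period
        assert lag_s % 1.0 == pytest.approx(expected, abs=1.5 / s.spec.fs)

    def test_skull_and_csf_static(self, default_series):
        assert np.ptp(default_series.alpha_db[:, 1:3], axis=0).max() == 0.0
        assert np.ptp(default_series.mua[:, 1:3], axis=0).max() == 0.0

    def test_absorption_modulation_depth(self, default_series):
        mua = default_series.mua[:, 3]
        dev = np.abs(mua / 0.017 - 1).max()
        assert dev == pytest.approx(0.03, rel=1e-6)

    def test_excessive_pulsatility_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_waveform(WaveformSpec(pulsatility_index=6.0), adult_head_preset())

    def test_morphologies_share_pulsatility(self):
        tri = make_waveform(
            WaveformSpec(morphology="triangular"), adult_head_preset()
        )
        a = tri.alpha_db[:, 3]
        assert (a.max() - a.min()) / a.mean() == pytest.approx(0.8, rel=0.01)
        assert not np.allclose(
            cardiac_pulse(np.linspace(0, 1, 50)), triangular_pulse(np.linspace(0, 1, 50))
        )


class TestEvaluateRecovery:
    def test_perfect_recovery(self, default_series):
        rec = _fake("TD", default_series.rcbf)
        r_cbf, r_sbf = evaluate_recovery(rec, default_series)
        assert r_cbf == pytest.approx(1.0)
        assert r_sbf < 1.0

    def test_anticorrelated(self, default_series):
        rec = _fake("TD", -default_series.rcbf)
        r_cbf, _ = evaluate_recovery(rec, default_series)
        assert r_cbf == pytest.approx(-1.0)

    def test_even_mixture(self, default_series):
        mix = 0.5 * default_series.rcbf + 0.5 * default_series.rsbf
        r_cbf, r_sbf = evaluate_recovery(_fake("TD", mix), default_series)
        expected_cbf = np.corrcoef(mix, default_series.rcbf)[0, 1]
        expected_sbf = np.corrcoef(mix, default_series.rsbf)[0, 1]
        assert (r_cbf, r_sbf) == pytest.approx((expected_cbf, expected_sbf))
        assert 0 < r_cbf < 1 and 0 < r_sbf < 1

    def test_zero_variance_rejected(self, default_series):
        with pytest.raises(ValueError, match="variance"):
            evaluate_recovery(_fake("TD", np.zeros(default_series.n_points)),
                              default_series)


def _fake(modality, rbfi):
    from dcsmc.pulsatile import RecoveredSeries

    return RecoveredSeries(modality, {}, np.asarray(rbfi))


class TestFindCrossing:
    def test_linear_pair_crosses_at_25(self):
        x = np.arange(0.0, 51.0, 5.0)
        pairs = np.column_stack([x / 50.0, 1 - x / 50.0])
        res = find_crossing(x, pairs)
        assert res.valid and res.crossing == pytest.approx(25.0)

    def test_sign_change_at_grid_point(self):
        x = np.array([1.0, 2.0, 3.0])
        pairs = np.array([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]])
        res = find_crossing(x, pairs)
        assert res.crossing == pytest.approx(2.0)

    def test_no_crossing_flagged_with_direction(self):
        x = np.array([1.0, 2.0])
        res = find_crossing(x, np.array([[0.9, 0.1], [0.8, 0.2]]))
        assert not res.valid and np.isnan(res.crossing)
        assert res.boundary_direction == "brain"

    def test_multiple_crossings_warn(self):
        x = np.arange(4.0)
        d = np.array([1.0, -1.0, 1.0, -1.0])
        pairs = np.column_stack([d, np.zeros(4)])
        with pytest.warns(UserWarning, match="sign changes"):
            res = find_crossing(x, pairs)
        assert res.valid and len(res.all_crossings) == 3
        assert res.crossing == pytest.approx(0.5)


@pytest.fixture(scope="module")
def short_series():
    return make_waveform(WaveformSpec(n_points=40), adult_head_preset())


@pytest.fixture(scope="module")
def static_series():
    return make_waveform(
        WaveformSpec(n_points=40, pulsatility_index=0.0, mua_mod_depth=0.0),
        adult_head_preset(),
    )


class TestTimeseriesReplay:
    @pytest.mark.parametrize(
        "cfg",
        [
            TDConfig(annulus=(5.0, 15.0), gate_center=0.5e-9),
            CWConfig(annulus=(5.0, 15.0)),
            SCOSConfig(annulus=(5.0, 15.0)),
        ],
        ids=["TD", "CW", "SCOS"],
    )
    def test_static_series_recovers_flat_rbfi(self, head_table, wl, static_series, cfg):
        rec = simulate_timeseries(head_table, static_series, cfg, wl)
        np.testing.assert_allclose(rec.rbfi, 0.0, atol=1e-9)

    def test_replay_matches_direct_surface_evaluation(self, head_table, wl, short_series):
        """The optimized replay equals evaluating the IRF-convolved gated
        surface time point by time point."""
        import math

        cfg = TDConfig(annulus=(5.0, 15.0), gate_center=0.51e-9)
        rec = simulate_timeseries(head_table, short_series, cfg, wl)
        tof_grid = ToFGrid.uniform(t_max=1.5e-9, width=cfg.tof_bin_width)
        irf = IRFKernel(cfg.irf_fwhm, cfg.tof_bin_width)
        gate_bin = math.floor(cfg.gate_center / cfg.tof_bin_width)
        from dcsmc.recovery import fit_td_decay, xi_to_alphadb

        for t in (0, 17, 39):
            state = FlowAbsorptionState(
                short_series.alpha_db[t], short_series.mua[t]
            )
            surf = convolve_irf(
                g1_surface(head_table, state, tof_grid,
                           LagGrid.log(cfg.tau_min, 1e-2, cfg.points_per_decade),
                           wl, annulus=cfg.annulus),
                irf,
            )
            g1_gate = surf.G1[gate_bin] / surf.G1[gate_bin, 0]
            fit = fit_td_decay(g1_gate, surf.lag_grid.lags)
            alpha_direct = xi_to_alphadb(
                fit.xi, cfg.gate_center, cfg.fit_mus_prime, cfg.fit_n,
                wl.lambda_vac,
            )
            assert rec.extras["alpha_db"][t] == pytest.approx(alpha_direct, rel=1e-6)

    def test_replay_deterministic(self, head_table, wl, short_series):
        cfg = SCOSConfig(annulus=(5.0, 15.0))
        a = simulate_timeseries(head_table, short_series, cfg, wl)
        b = simulate_timeseries(head_table, short_series, cfg, wl)
        np.testing.assert_array_equal(a.rbfi, b.rbfi)

    def test_pulsatile_flow_produces_pulsatile_rbfi(self, head_table, wl, short_series):
        cfg = TDConfig(annulus=(5.0, 15.0), gate_center=0.6e-9)
        rec = simulate_timeseries(head_table, short_series, cfg, wl)
        assert np.ptp(rec.rbfi) > 0.05
        r_cbf, r_sbf = evaluate_recovery(rec, short_series)
        # a short-SDS early gate is scalp-dominated
        assert r_sbf > r_cbf

    @pytest.mark.parametrize(
        "cfg",
        [CWConfig(annulus=(5.0, 15.0)), SCOSConfig(annulus=(5.0, 15.0))],
        ids=["CW", "SCOS"],
    )
    def test_short_sds_cw_and_scos_are_scalp_dominated(
        self, head_table, wl, short_series, cfg
    ):
        rec = simulate_timeseries(head_table, short_series, cfg, wl)
        r_cbf, r_sbf = evaluate_recovery(rec, short_series)
        assert r_sbf > r_cbf

    def test_empty_gate_rejected(self, head_table, wl, short_series):
        cfg = TDConfig(annulus=(5.0, 15.0), gate_center=40e-9)
        with pytest.raises(ValueError, match="empty photon selection"):
            simulate_timeseries(head_table, short_series, cfg, wl)


class TestDepthSweep:
    def test_one_transport_and_crossing_per_depth(self, wl):
        """Plumbing check: the sweep builds one medium per distance-to-brain
        (skull thickness varied, scalp 4 mm / CSF 2 mm fixed), runs one
        transport each, and collects the crossing results."""
        seen_media = []

        def fake_transport(medium):
            seen_media.append(medium)
            return object()

        def fake_crossing(table, series, wavelength):
            depth = seen_media[-1].boundaries[3]
            return CrossingResult(
                np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                np.array([1.0, 0.0]), depth * 0.05, True,
            )

        out = depth_sweep(
            [10.0, 14.0], wl, fake_transport, fake_crossing,
            spec=WaveformSpec(n_points=50),
        )
        assert [d for d, _ in out] == [10.0, 14.0]
        assert len(seen_media) == 2
        for (depth, res), med in zip(out, seen_media):
            assert med.boundaries[3] == pytest.approx(depth)
            assert med.layers[0].thickness == 4.0
            assert med.layers[2].thickness == 2.0
            assert res.crossing == pytest.approx(depth * 0.05)
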