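"""Field-autocorrelation synthesis: hand-checked values, brute-force
equivalence, IRF convolution, ToF integration, Siegert, speckle contrast,
and log-lag resampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcsmc.forward import (
    FlowAbsorptionState,
    IRFKernel,
    LagGrid,
    ToFGrid,
    convolve_irf,
    g1_surface,
    resample_log_lags,
    siegert,
    speckle_contrast,
    tof_integrate,
)
from dcsmc.medium import adult_head_preset, wavelength_1064
from dcsmc.oracles import brute_force_g1, synthetic_table


def _surface(table, state, lags=None, **kw):
    wl = wavelength_1064()
    lag_grid = LagGrid(lags) if lags is not None else LagGrid.log(1e-8, 1e-2, 20)
    tof_grid = kw.pop("tof_grid", ToFGrid.uniform(t_max=3e-9))
    return g1_surface(table, state, tof_grid, lag_grid, wl, **kw)


class TestG1Surface:
    def test_single_photon_hand_value(self, wl):
        """One photon, Y = [10,0,0,50], αDB = [1e-6,0,0,5e-6], all n = 1.4:
        g1(1 μs) = exp(−2 k0² · 1e-6 · (10·1e-6 + 50·5e-6)) ≈ 0.9651."""
        med = adult_head_preset()
        # force a uniform index so a single k0 = 2π·1.4/λ applies
        table = synthetic_table(
            med, [[10.0, 0, 0, 10.0]], [[10.0, 0.0, 0.0, 50.0]]
        )
        state = FlowAbsorptionState([1e-6, 0, 0, 5e-6], np.zeros(4))
        surf = _surface(table, state, lags=np.array([0.0, 1e-6]))
        g1 = surf.g1()[surf.occupied][0]
        k0 = wl.k0(1.4)
        expected = math.exp(-2 * k0**2 * 1e-6 * (10e-6 + 250e-6))
        assert g1[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9651, abs=2e-4)

    def test_static_state_gives_unity_g1(self, random_table):
        state = FlowAbsorptionState(np.zeros(4), np.full(4, 0.01))
        surf = _surface(random_table, state)
        g1 = surf.g1()[surf.occupied]
        np.testing.assert_allclose(g1, 1.0, atol=1e-14)

    def test_tau0_column_is_weighted_tpsf(self, random_table):
        state = FlowAbsorptionState(np.full(4, 1e-6), np.full(4, 0.012))
        surf = _surface(random_table, state)
        w = np.exp(-random_table.partial_path @ state.mua)
        edges = surf.tof_grid.edges
        idx = np.digitize(random_table.tof, edges) - 1
        expected = np.zeros(surf.tof_grid.n_bins)
        for i, b in enumerate(idx):
            if 0 <= b < expected.size:
                expected[b] += w[i]
        np.testing.assert_allclose(
            surf.tpsf(), expected / random_table.n_detected, rtol=1e-12
        )

    def test_matches_brute_force_loop(self, random_table, wl):
        state = FlowAbsorptionState(
            np.array([1e-6, 2e-8, 5e-8, 5e-6]), np.array([0.012, 0.013, 0.012, 0.017])
        )
        lags = np.array([0.0, 1e-7, 1e-6, 1e-5, 1e-4])
        # pool all ToF into one wide bin so the surface equals the CW loop
        surf = _surface(
            random_table, state, lags=lags,
            tof_grid=ToFGrid(np.array([0.0, 1.0])),
        )
        expected = brute_force_g1(
            random_table.partial_path,
            random_table.momentum_transfer,
            state.mua,
            state.alpha_db,
            random_table.medium.k0(wl),
            lags,
        )
        np.testing.assert_allclose(surf.G1[0], expected, rtol=1e-12)

    def test_monotone_nonincreasing_in_lag(self, random_table):
        state = FlowAbsorptionState(np.full(4, 3e-6), np.full(4, 0.012))
        surf = _surface(random_table, state)
        g1 = surf.g1()[surf.occupied]
        assert np.all(np.diff(g1, axis=1) <= 1e-15)

    @settings(derandomize=True, max_examples=30)
    @given(
        bump=st.floats(1e-8, 1e-4),
        layer=st.integers(0, 3),
        tau_idx=st.integers(1, 10),
    )
    def test_increasing_alpha_never_increases_g1(self, random_table_factory,
                                                 bump, layer, tau_idx):
        table = random_table_factory
        base = np.array([1e-6, 2e-8, 5e-8, 5e-6])
        lags = np.concatenate([[0.0], np.geomspace(1e-8, 1e-3, 12)])
        lo = _surface(table, FlowAbsorptionState(base, np.zeros(4)), lags=lags)
        hi_alpha = base.copy()
        hi_alpha[layer] += bump
        hi = _surface(table, FlowAbsorptionState(hi_alpha, np.zeros(4)), lags=lags)
        occ = lo.occupied
        assert np.all(hi.g1()[occ][:, tau_idx] <= lo.g1()[occ][:, tau_idx] + 1e-15)


@pytest.fixture(scope="module")
def random_table_factory(wl):
    med = adult_head_preset()
    rng = np.random.default_rng(77)
    L = rng.exponential(15.0, size=(300, 4))
    Y = rng.exponential(25.0, size=(300, 4))
    return synthetic_table(med, L, Y)


class TestIRFConvolution:
    def _one_bin_surface(self, random_table, fwhm_ok=True):
        state = FlowAbsorptionState(np.full(4, 1e-6), np.zeros(4))
        return _surface(random_table, state)

    def test_delta_irf_is_identity(self, random_table):
        surf = self._one_bin_surface(random_table)
        with pytest.warns(UserWarning, match="identity"):
            out = convolve_irf(surf, IRFKernel(1e-12, surf.tof_grid.width))
        np.testing.assert_array_equal(out.G1, surf.G1)

    def test_total_weight_conserved(self, wl):
        # signal constructed to live >= 4 sigma away from both grid edges
        med = adult_head_preset()
        rng = np.random.default_rng(5)
        L = 30.0 + rng.exponential(10.0, size=(200, 4))
        table = synthetic_table(med, L, rng.exponential(25.0, size=(200, 4)))
        assert table.tof.min() > 0.3e-9 and table.tof.max() < 2.7e-9
        state = FlowAbsorptionState(np.full(4, 1e-6), np.zeros(4))
        surf = _surface(table, state)
        out = convolve_irf(surf, IRFKernel(125e-12, surf.tof_grid.width))
        assert out.G1[:, 0].sum() == pytest.approx(surf.G1[:, 0].sum(), rel=1e-9)

    def test_single_bin_spreads_to_gaussian(self, wl):
        med = adult_head_preset()
        # one photon whose ToF lands mid-grid
        L = np.zeros((1, 4))
        L[0, 0] = 321.4  # n=1.4 -> tof ≈ 1.5 ns
        table = synthetic_table(med, L, np.zeros((1, 4)))
        state = FlowAbsorptionState(np.zeros(4), np.zeros(4))
        surf = _surface(table, state)
        fwhm = 125e-12
        out = convolve_irf(surf, IRFKernel(fwhm, surf.tof_grid.width))
        tpsf = out.tpsf()
        src = int(np.argmax(surf.tpsf()))
        # direct discrete convolution oracle: normalized Gaussian on ±4σ
        sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
        width = surf.tof_grid.width
        half = math.ceil(4 * sigma / width)
        kern = np.exp(-0.5 * ((np.arange(-half, half + 1) * width) / sigma) ** 2)
        kern /= kern.sum()
        expected = np.zeros_like(tpsf)
        expected[src - half : src + half + 1] = kern * surf.tpsf().sum()
        np.testing.assert_allclose(tpsf, expected, atol=1e-12)


class TestToFIntegrate:
    def test_static_surface_integrates_to_unity(self, random_table):
        state = FlowAbsorptionState(np.zeros(4), np.full(4, 0.012))
        g1 = tof_integrate(_surface(random_table, state))
        np.testing.assert_allclose(g1, 1.0, atol=1e-14)

    def test_two_bin_mixture_hand_value(self, wl):
        med = adult_head_preset()
        L = np.zeros((2, 4))
        L[0, 0] = 40.0   # early photon
        L[1, 0] = 150.0  # late photon
        Y = np.zeros((2, 4))
        Y[0, 0] = 10.0
        Y[1, 0] = 100.0
        table = synthetic_table(med, L, Y)
        state = FlowAbsorptionState([1e-6, 0, 0, 0], np.zeros(4))
        lags = np.array([0.0, 1e-6])
        g1 = tof_integrate(_surface(table, state, lags=lags))
        k0 = wl.k0(1.4)
        e1 = math.exp(-2 * k0**2 * 1e-6 * 10e-6)
        e2 = math.exp(-2 * k0**2 * 1e-6 * 100e-6)
        assert g1[1] == pytest.approx((e1 + e2) / 2, rel=1e-12)


def test_siegert_values():
    assert siegert(1.0, 0.5) == pytest.approx(1.5)
    assert siegert(0.0, 0.9) == pytest.approx(1.0)
    assert siegert(0.5, 0.5) == pytest.approx(1.125)
    with pytest.raises(ValueError):
        siegert(0.5, 1.5)


class TestSpeckleContrast:
    def _grid(self, tmax=1e-2):
        return np.concatenate([[0.0], np.geomspace(1e-10, tmax, 600)])

    def test_unity_g1_gives_beta(self):
        lags = self._grid()
        k2 = speckle_contrast(np.ones_like(lags), lags, T=250e-6, beta=0.7)
        assert k2 == pytest.approx(0.7, rel=1e-6)

    def test_single_exponential_closed_form(self):
        tau_c, T = 10e-6, 250e-6
        lags = self._grid()
        g1 = np.exp(-lags / tau_c)
        x = T / tau_c
        expected = (math.exp(-2 * x) - 1 + 2 * x) / (2 * x**2)
        assert expected == pytest.approx(49 / 1250)
        assert speckle_contrast(g1, lags, T, beta=1.0) == pytest.approx(
            expected, rel=1e-3
        )

    def test_short_exposure_limit(self):
        lags = self._grid()
        g1 = np.exp(-lags / 10e-6)
        assert speckle_contrast(g1, lags, T=1e-9, beta=1.0) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_exposure_outside_grid_rejected(self):
        lags = self._grid(tmax=1e-5)
        with pytest.raises(ValueError):
            speckle_contrast(np.ones_like(lags), lags, T=1e-3)


class TestLogResampling:
    def test_exponential_interpolation_error(self, random_table):
        state = FlowAbsorptionState(np.full(4, 2e-6), np.zeros(4))
        surf = _surface(random_table, state,
                        lags=np.concatenate([[0.0], np.geomspace(1e-8, 1e-3, 400)]))
        coarse = resample_log_lags(surf, points_per_decade=15)
        # evaluate the resampled curve back on the original nodes
        occ = np.where(surf.occupied)[0][:5]
        for b in occ:
            back = np.interp(
                np.log(surf.lag_grid.positive),
                np.log(coarse.lag_grid.positive),
                coarse.g1()[b, 1:],
            )
            assert np.max(np.abs(back - surf.g1()[b, 1:])) < 1e-3

    def test_monotonicity_preserved(self, random_table):
        state = FlowAbsorptionState(np.full(4, 2e-6), np.zeros(4))
        surf = _surface(random_table, state)
        out = resample_log_lags(surf, points_per_decade=33)
        g1 = out.g1()[out.G1[:, 0] > 0]
        assert np.all(np.diff(g1, axis=1) <= 1e-12)

    def test_endpoints_preserved(self, random_table):
        state = FlowAbsorptionState(np.full(4, 2e-6), np.zeros(4))
        surf = _surface(random_table, state)
        out = resample_log_lags(surf, points_per_decade=40)
        assert out.lag_grid.positive[0] == surf.lag_grid.positive[0]
        assert out.lag_grid.positive[-1] == surf.lag_grid.positive[-1]
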