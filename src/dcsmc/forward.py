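"""ToF-resolved field-autocorrelation synthesis and derived observables.

Given a photon lookup table and a per-layer flow/absorption state, the
un-normalized field autocorrelation on a (ToF bin × lag) grid is

    G1(ts, τ) = (1/Np) Σ_p w_p · exp(−2 τ Σ_n k0,n² Y_p,n αDB,n),

with absorption weights w_p = exp(−Σ_n μa,n L_p,n) and Np the number of
detected photons.  The exponent is the mean-squared-displacement form
(1/3)·k0²·Y·⟨Δr²(τ)⟩ with Brownian motion ⟨Δr²⟩ = 6 αDB τ collapsed
algebraically.  The τ = 0 column is the absorption-weighted TPSF.

From the surface the three modality observables follow: the CW field
autocorrelation (ToF integral), the intensity autocorrelation g2 via the
Siegert relation, and the SCOS squared speckle contrast K²(T).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import PchipInterpolator

from ._kernels import accumulate_g1
from .medium import LayeredMedium, SimulationWavelength
from .transport import PhotonTable

__all__ = [
    "FlowAbsorptionState",
    "LagGrid",
    "ToFGrid",
    "IRFKernel",
    "CorrelationSurface",
    "photon_weights",
    "decay_rates",
    "g1_surface",
    "convolve_irf",
    "tof_integrate",
    "siegert",
    "speckle_contrast",
    "resample_log_lags",
    "integrate_0_to_T",
]


@dataclass(frozen=True)
class FlowAbsorptionState:
    """Per-layer αDB (mm² s⁻¹) and μa (mm⁻¹) at one instant.

    This is the replay knob of the white-Monte-Carlo design: one photon
    table serves every state.
    """

    alpha_db: np.ndarray
    mua: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alpha_db, dtype=float))
        m = np.atleast_1d(np.asarray(self.mua, dtype=float))
        if a.shape != m.shape:
            raise ValueError("alpha_db and mua must have equal length")
        if np.any(a < 0) or np.any(m < 0):
            raise ValueError("alpha_db and mua must be nonnegative")
        object.__setattr__(self, "alpha_db", a)
        object.__setattr__(self, "mua", m)

    @classmethod
    def from_medium(cls, medium: LayeredMedium) -> "FlowAbsorptionState":
        return cls(medium.prop("alpha_db"), medium.prop("mua"))

    @property
    def n_layers(self) -> int:
        return self.alpha_db.shape[0]


@dataclass(frozen=True)
class LagGrid:
    """Autocorrelation lag grid: τ = 0 followed by log-spaced lags (s)."""

    lags: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        if lags.size < 1 or lags[0] != 0.0:
            raise ValueError("lag grid must start at τ = 0")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)

    @classmethod
    def log(
        cls,
        tau_min: float = 1e-8,
        tau_max: float = 1.0,
        per_decade: int = 40,
    ) -> "LagGrid":
        """τ = 0 plus ``per_decade`` log-spaced points per decade on
        [tau_min, tau_max]."""
        n_dec = math.log10(tau_max / tau_min)
        n = max(2, int(round(n_dec * per_decade)) + 1)
        return cls(np.concatenate([[0.0], np.geomspace(tau_min, tau_max, n)]))

    @property
    def positive(self) -> np.ndarray:
        return self.lags[1:]


@dataclass(frozen=True)
class ToFGrid:
    """Uniform-width ToF bin edges (s)."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        widths = np.diff(e)
        if e.size < 2 or np.any(widths <= 0):
            raise ValueError("ToF edges must be increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("ToF bins must have uniform width")
        object.__setattr__(self, "edges", e)

    @classmethod
    def uniform(cls, t_max: float = 3e-9, width: float = 25e-12) -> "ToFGrid":
        n = int(round(t_max / width))
        return cls(np.linspace(0.0, n * width, n + 1))

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclass(frozen=True)
class IRFKernel:
    """Gaussian instrument-response surrogate along the ToF axis.

    Only the FWHM of the hardware IRF is modelled (default 125 ps); the
    kernel is discretized on the ToF bin width, truncated at ±4σ, and
    normalized to unit sum so convolution conserves total weight away from
    the grid edges.
    """

    fwhm: float
    bin_width: float

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def weights(self) -> np.ndarray:
        if self.fwhm < self.bin_width:
            warnings.warn(
                "IRF FWHM below the ToF bin width: kernel degenerates to "
                "identity",
                stacklevel=2,
            )
            return np.array([1.0])
        half = max(1, int(math.ceil(4.0 * self.sigma / self.bin_width)))
        t = np.arange(-half, half + 1) * self.bin_width
        w = np.exp(-0.5 * (t / self.sigma) ** 2)
        return w / w.sum()


@dataclass
class CorrelationSurface:
    """Un-normalized G1 on a (ToF bin × lag) grid plus provenance.

    ``G1[b, 0]`` is the absorption-weighted TPSF; ``counts[b]`` the raw
    photon count per bin (zero marks an empty bin).
    """

    G1: np.ndarray
    counts: np.ndarray
    tof_grid: ToFGrid
    lag_grid: LagGrid
    state: FlowAbsorptionState
    beta: float = 1.0

    def g1(self) -> np.ndarray:
        """Normalized g1 = G1(ts, τ)/G1(ts, 0); zero rows for empty bins."""
        out = np.zeros_like(self.G1)
        occ = self.G1[:, 0] > 0
        out[occ] = self.G1[occ] / self.G1[occ, :1]
        return out

    def tpsf(self) -> np.ndarray:
        return self.G1[:, 0]

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def photon_weights(table: PhotonTable, state: FlowAbsorptionState) -> np.ndarray:
    """Absorption weights w_p = exp(−Σ_n μa,n L_p,n)."""
    return np.exp(-table.partial_path @ state.mua)


def decay_rates(
    table: PhotonTable,
    state: FlowAbsorptionState,
    wavelength: SimulationWavelength,
) -> np.ndarray:
    """Per-photon decay-rate coefficient 2 Σ_n k0,n² Y_p,n αDB,n (s⁻¹).

    The per-layer wavenumber k0,n = 2π n_n/λ is applied inside the layer
    sum, consistent with Y being accumulated per layer.
    """
    k0 = table.medium.k0(wavelength)
    return 2.0 * table.momentum_transfer @ (k0**2 * state.alpha_db)


def g1_surface(
    table: PhotonTable,
    state: FlowAbsorptionState,
    tof_grid: ToFGrid,
    lag_grid: LagGrid,
    wavelength: SimulationWavelength,
    annulus: tuple[float, float] | None = None,
) -> CorrelationSurface:
    """Synthesize the ToF-resolved G1 surface for one flow/absorption state.

    ``annulus = (r_in, r_out)`` restricts to photons detected in that exit
    ring; by default all detected photons are used.  Raises if every ToF bin
    is empty.
    """
    if state.n_layers != table.medium.n_layers:
        raise ValueError("state length does not match the table's medium")
    mask = (
        table.select_annulus(*annulus)
        if annulus is not None
        else np.ones(table.n_detected, dtype=bool)
    )
    w = photon_weights(table, state)[mask]
    rate = decay_rates(table, state, wavelength)[mask]
    tof = table.tof[mask]
    edges = tof_grid.edges
    bin_idx = np.floor((tof - edges[0]) / tof_grid.width).astype(np.int64)
    bin_idx[(tof < edges[0]) | (tof >= edges[-1])] = -1
    G1, counts = accumulate_g1(
        bin_idx, w, rate, lag_grid.lags, tof_grid.n_bins
    )
    if not np.any(counts > 0):
        raise ValueError("all ToF bins are empty for this table/grid")
    n_total = int(mask.sum())
    return CorrelationSurface(
        G1=G1 / n_total,
        counts=counts,
        tof_grid=tof_grid,
        lag_grid=lag_grid,
        state=state,
    )


def convolve_irf(surface: CorrelationSurface, irf: IRFKernel) -> CorrelationSurface:
    """Convolve every lag column (and the TPSF) along the ToF axis.

    The kernel must be built on the surface's ToF bin width.  Total weight
    is conserved for signal supported ≥ 4σ away from the grid edges.
    """
    if not math.isclose(irf.bin_width, surface.tof_grid.width, rel_tol=1e-9):
        raise ValueError("IRF support grid does not match the ToF bin width")
    w = irf.weights
    if w.size == 1:
        return surface
    half = w.size // 2
    padded = np.pad(surface.G1, ((half, half), (0, 0)))
    out = np.empty_like(surface.G1)
    for j in range(surface.G1.shape[1]):
        out[:, j] = np.convolve(padded[:, j], w, mode="valid")
    # counts spread the same way (fractional effective counts)
    cpad = np.pad(surface.counts.astype(float), (half, half))
    counts = np.convolve(cpad, w, mode="valid")
    return replace(surface, G1=out, counts=counts)


def tof_integrate(surface: CorrelationSurface) -> np.ndarray:
    """CW field autocorrelation: sum G1 over ToF, normalized at τ = 0."""
    G = surface.G1.sum(axis=0)
    if G[0] <= 0:
        raise ValueError("empty surface: no weight at τ = 0")
    return G / G[0]


def siegert(g1_value, beta: float):
    """Siegert relation g2 = 1 + β·|g1|²."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    return 1.0 + beta * np.abs(np.asarray(g1_value)) ** 2


def integrate_0_to_T(y: np.ndarray, lags: np.ndarray, T: float) -> float:
    """∫₀ᵀ y dτ by composite Simpson on the (log-aware) grid restricted to
    [0, T], with the endpoint at T interpolated and a trapezoid fallback for
    fewer than 3 nodes."""
    if T > lags[-1] or T <= 0:
        raise ValueError("exposure T outside the lag grid coverage")
    inside = lags < T
    x = np.concatenate([lags[inside], [T]])
    yT = np.interp(T, lags, y)
    yy = np.concatenate([y[inside], [yT]])
    if x.size < 3:
        return float(np.trapezoid(yy, x))
    return float(simpson(yy, x=x))


def speckle_contrast(
    g1_curve: np.ndarray,
    lags: np.ndarray,
    T: float,
    beta: float = 1.0,
) -> float:
    """Squared speckle contrast K²(T) = (2β/T)·∫₀ᵀ (1 − τ/T)|g1|² dτ."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    integrand = (1.0 - lags / T) * np.abs(g1_curve) ** 2
    return 2.0 * beta / T * integrate_0_to_T(integrand, lags, T)


def resample_log_lags(
    surface: CorrelationSurface,
    points_per_decade: int = 40,
    tau_min: float | None = None,
) -> CorrelationSurface:
    """Resample g1 from its lag axis onto a log-spaced grid.

    Monotone (PCHIP) interpolation in log-τ preserves the non-increasing
    shape of g1; grid endpoints are preserved.  ``tau_min`` defaults to the
    first positive lag.
    """
    old = surface.lag_grid.positive
    if old.size < 2:
        raise ValueError("need at least 2 positive lags to resample")
    lo = old[0] if tau_min is None else tau_min
    if lo < old[0] or lo >= old[-1]:
        raise ValueError("tau_min outside the original lag range")
    n_dec = math.log10(old[-1] / lo)
    n = max(2, int(round(n_dec * points_per_decade)) + 1)
    new = np.geomspace(lo, old[-1], n)
    new[-1] = old[-1]  # exact endpoint
    out = np.empty((surface.G1.shape[0], n + 1))
    out[:, 0] = surface.G1[:, 0]
    logx = np.log(old)
    for b in range(surface.G1.shape[0]):
        if surface.G1[b, 0] <= 0:
            out[b, 1:] = 0.0
            continue
        interp = PchipInterpolator(logx, surface.G1[b, 1:])
        out[b, 1:] = interp(np.log(new))
    return replace(
        surface, G1=out, lag_grid=LagGrid(np.concatenate([[0.0], new]))
    )
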