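"""Numba-compiled hot loops: photon transport and autocorrelation sums.

These kernels are deliberately free of Python objects; all medium and grid
information arrives as flat float64 arrays.  The transport kernel uses the
legacy NumPy global RNG inside nopython mode, seeded per chunk, which makes a
run deterministic for a fixed (seed, chunk-size) pair on a single thread.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _sample_hg(g: float) -> float:
    """Sample cosθ from the Henyey–Greenstein phase function."""
    u = np.random.random()
    if g < 1e-6:
        return 1.0 - 2.0 * u
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


@njit(cache=True, fastmath=True)
def _fresnel_r(n1: float, n2: float, cos_i: float, cos_t: float) -> float:
    """Unpolarized Fresnel reflectance for given incidence/transmission cosines."""
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def transport_chunk(
    n_photons: int,
    seed: int,
    zb: np.ndarray,       # interface depths, length n_layers + 1, zb[0] = 0
    mus: np.ndarray,      # per-layer scattering coefficient (mm^-1)
    g: np.ndarray,        # per-layer anisotropy
    n_layer: np.ndarray,  # per-layer refractive index
    ambient_n: float,
    max_tof: float,
    max_radius: float,
    c_vac: float,
    out_r: np.ndarray,    # (n_photons,)
    out_L: np.ndarray,    # (n_photons, n_layers)
    out_Y: np.ndarray,    # (n_photons, n_layers)
    out_tof: np.ndarray,  # (n_photons,)
) -> int:
    """Trace ``n_photons`` pencil-beam photons; return the detected count.

    Scattering-only (white Monte Carlo) transport through a layered slab:
    exponential free paths with the local μs, Henyey–Greenstein deflections
    with the local g, Snell/Fresnel interfaces with total internal reflection.
    Per-layer pathlength and Σ(1−cosθ) momentum transfer are recorded for
    every photon that exits the top surface within ``max_radius``.  Photons
    are discarded when their ToF exceeds ``max_tof``, their lateral radius
    exceeds ``max_radius``, or they exit the bottom of the deepest layer.
    """
    np.random.seed(seed)
    nm = mus.shape[0]
    count = 0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        tof = 0.0
        for m in range(nm):
            out_L[count, m] = 0.0
            out_Y[count, m] = 0.0
        alive = True
        detected = False
        while alive:
            # dimensionless step (units of scattering mean free paths)
            s_left = -math.log(np.random.random())
            while s_left > 0.0 and alive:
                step = s_left / mus[layer]
                # distance to the bounding interface along the flight direction
                if uz > 0.0:
                    d_bound = (zb[layer + 1] - z) / uz
                elif uz < 0.0:
                    d_bound = (zb[layer] - z) / uz
                else:
                    d_bound = 1e30
                if d_bound < step:
                    # advance to the interface
                    x += ux * d_bound
                    y += uy * d_bound
                    out_L[count, layer] += d_bound
                    tof += d_bound * n_layer[layer] / c_vac
                    s_left -= d_bound * mus[layer]
                    if tof > max_tof or x * x + y * y > max_radius * max_radius:
                        alive = False
                        break
                    going_up = uz < 0.0
                    if going_up:
                        z = zb[layer]
                        n2 = ambient_n if layer == 0 else n_layer[layer - 1]
                    else:
                        z = zb[layer + 1]
                        n2 = n_layer[layer + 1] if layer < nm - 1 else n_layer[layer]
                        if layer == nm - 1:
                            # exits the bottom of the deepest layer: discard
                            alive = False
                            break
                    n1 = n_layer[layer]
                    cos_i = abs(uz)
                    if n1 == n2:
                        refl = 0.0
                        cos_t = cos_i
                    else:
                        sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
                        if sin_t2 >= 1.0:
                            refl = 1.0  # total internal reflection
                            cos_t = 0.0
                        else:
                            cos_t = math.sqrt(1.0 - sin_t2)
                            refl = _fresnel_r(n1, n2, cos_i, cos_t)
                    if np.random.random() < refl:
                        uz = -uz  # specular reflection, stay in layer
                    else:
                        # refract
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = cos_t if uz > 0.0 else -cos_t
                        if going_up and layer == 0:
                            # transmitted through the top surface: detected
                            r = math.sqrt(x * x + y * y)
                            if r <= max_radius:
                                out_r[count] = r
                                out_tof[count] = tof
                                detected = True
                            alive = False
                            break
                        # the dimensionless remaining step carries over unchanged
                        layer = layer - 1 if going_up else layer + 1
                else:
                    # full step inside the layer, then scatter
                    x += ux * step
                    y += uy * step
                    z += uz * step
                    out_L[count, layer] += step
                    tof += step * n_layer[layer] / c_vac
                    s_left = 0.0
                    if tof > max_tof or x * x + y * y > max_radius * max_radius:
                        alive = False
                        break
                    cost = _sample_hg(g[layer])
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                    out_Y[count, layer] += 1.0 - cost
                    sint = math.sqrt(1.0 - cost * cost)
                    phi = 2.0 * math.pi * np.random.random()
                    cosp = math.cos(phi)
                    sinp = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        tmp = math.sqrt(1.0 - uz * uz)
                        ux_n = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
                        uy_n = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
                        uz_n = -sint * cosp * tmp + uz * cost
                        norm = math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                        ux = ux_n / norm
                        uy = uy_n / norm
                        uz = uz_n / norm
        if detected:
            count += 1
    return count


@njit(cache=True)
def accumulate_g1(
    bin_idx: np.ndarray,   # (P,) ToF bin index per photon, -1 = outside grid
    w: np.ndarray,         # (P,) absorption weights
    rate: np.ndarray,      # (P,) decay-rate coefficient 2 Σ_n k0n² Y_pn αDB,n
    lags: np.ndarray,      # (K,) lag grid, lags[0] may be 0
    n_bins: int,
):
    """Accumulate un-normalized G1 over a (ToF bin × lag) grid.

    G1[b, k] = Σ_{p in bin b} w_p · exp(−rate_p · τ_k).
    Also returns per-bin photon counts.
    """
    K = lags.shape[0]
    G1 = np.zeros((n_bins, K))
    counts = np.zeros(n_bins, dtype=np.int64)
    for p in range(bin_idx.shape[0]):
        b = bin_idx[p]
        if b < 0:
            continue
        counts[b] += 1
        wp = w[p]
        rp = rate[p]
        for k in range(K):
            G1[b, k] += wp * math.exp(-rp * lags[k])
    return G1, counts


@njit(cache=True)
def g1_and_dg1(
    w: np.ndarray,     # (P,) weights (absorption × any gate/IRF weight)
    rate: np.ndarray,  # (P,) decay-rate coefficient
    Q: np.ndarray,     # (P, Nm) per-layer 2 k0n² Y_pn (d rate / d αDB,n)
    lags: np.ndarray,  # (K,)
):
    """Return (G1(τ), dG1/dαDB,n(τ)) summed over the photon selection.

    dG1/dαDB,m(τ) = Σ_p w_p · (−Q_pm τ) · exp(−rate_p τ).
    """
    P, Nm = Q.shape
    K = lags.shape[0]
    G1 = np.zeros(K)
    D = np.zeros((Nm, K))
    for p in range(P):
        wp = w[p]
        rp = rate[p]
        for k in range(K):
            e = wp * math.exp(-rp * lags[k])
            G1[k] += e
            for m in range(Nm):
                D[m, k] -= Q[p, m] * lags[k] * e
    return G1, D


@njit(cache=True, fastmath=True)
def g1_replay(
    L: np.ndarray,        # (P, Nm) per-layer partial pathlengths
    Q: np.ndarray,        # (P, Nm) per-layer 2 k0n² Y_pn
    w0: np.ndarray,       # (P,) static weights (gate/IRF); absorption applied here
    mua_t: np.ndarray,    # (T, Nm) per-time-point absorption coefficients
    alpha_t: np.ndarray,  # (T, Nm) per-time-point αDB
    lags: np.ndarray,     # (K,)
):
    """Replay one photon selection over a pulsatile time series.

    Returns (G10, G1) with G10[t] = Σ_p w_p(t) and
    G1[t, k] = Σ_p w_p(t)·exp(−rate_p(t)·τ_k), where
    w_p(t) = w0_p·exp(−Σ_n L_pn μa,n(t)) and rate_p(t) = Σ_n Q_pn αDB,n(t).
    """
    P, Nm = L.shape
    T = mua_t.shape[0]
    K = lags.shape[0]
    G1 = np.zeros((T, K))
    G10 = np.zeros(T)
    for p in range(P):
        for t in range(T):
            a = 0.0
            r = 0.0
            for m in range(Nm):
                a += L[p, m] * mua_t[t, m]
                r += Q[p, m] * alpha_t[t, m]
            wp = w0[p] * math.exp(-a)
            G10[t] += wp
            for k in range(K):
                G1[t, k] += wp * math.exp(-r * lags[k])
    return G10, G1
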