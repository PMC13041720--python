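"""Independent closed-form and brute-force reference implementations.

These exist solely to validate the main modules in the test suite; they
share no code with the vectorized/compiled paths they check (plain-Python
loops and scalar arithmetic throughout).  Not part of the CLI surface.
"""

from __future__ import annotations

import math

import numpy as np

from .medium import C_VAC_MM_S, LayeredMedium
from .transport import PhotonTable, TransportConfig

__all__ = [
    "dws_xi_oracle",
    "semiinfinite_cw_g1_oracle",
    "brute_force_g1",
    "synthetic_table",
]


def dws_xi_oracle(
    mus_prime: float,
    n: float,
    lambda_vac: float,
    alpha_db: float,
    ts: float,
    c_vac: float = C_VAC_MM_S,
) -> float:
    """Homogeneous diffusing-wave decay coefficient ξ = 2k²μs′(c/n)αDB·ts."""
    k = 2.0 * math.pi * n / lambda_vac
    return 2.0 * k * k * mus_prime * (c_vac / n) * alpha_db * ts


def semiinfinite_cw_g1_oracle(
    mua: float,
    mus_prime: float,
    n: float,
    sds: float,
    alpha_db: float,
    lags,
    lambda_vac: float,
    n_out: float = 1.0,
) -> np.ndarray:
    """Semi-infinite extrapolated-boundary correlation-diffusion g1(τ).

    Scalar re-derivation, kept deliberately separate from the model inside
    the CW fitting routine: source at one transport mean free path, image
    source mirrored across the extrapolated boundary, decay wavevector
    K(τ) = sqrt(3μaμs′ + 6μs′²k²αDBτ), normalized at τ = 0.
    """
    k_med = 2.0 * math.pi * n / lambda_vac
    ratio = n / n_out
    # effective reflection coefficient (polynomial fit in the index ratio)
    r_eff = 0.0636 * ratio + 0.668 + 0.710 / ratio - 1.440 / ratio**2
    ell = 1.0 / mus_prime
    z_b = (2.0 / 3.0) * ell * (1.0 + r_eff) / (1.0 - r_eff)
    rho1 = math.sqrt(sds * sds + ell * ell)
    rho2 = math.sqrt(sds * sds + (ell + 2.0 * z_b) ** 2)

    def unnorm(tau: float) -> float:
        kd = math.sqrt(
            3.0 * mua * mus_prime
            + 6.0 * (mus_prime**2) * (k_med**2) * alpha_db * tau
        )
        return math.exp(-kd * rho1) / rho1 - math.exp(-kd * rho2) / rho2

    g0 = unnorm(0.0)
    return np.array([unnorm(float(t)) / g0 for t in np.atleast_1d(lags)])


def brute_force_g1(
    partial_path,
    momentum_transfer,
    mua,
    alpha_db,
    k0_per_layer,
    lags,
) -> np.ndarray:
    """Naive per-photon loop evaluation of the ToF-pooled field
    autocorrelation (no vectorization): equivalence oracle for the compiled
    accumulation kernels.

    G1(τ) = (1/Np) Σ_p exp(−Σ_n μa,n L_pn) · exp(−2τ Σ_n k0,n² Y_pn αDB,n).
    Returns an empty array for an empty lag list.
    """
    L = np.atleast_2d(np.asarray(partial_path, dtype=float))
    Y = np.atleast_2d(np.asarray(momentum_transfer, dtype=float))
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if lags.size == 0:
        return np.empty(0)
    out = []
    for tau in lags:
        acc = 0.0
        for p in range(L.shape[0]):
            w = 1.0
            s = 0.0
            for m in range(L.shape[1]):
                w *= math.exp(-mua[m] * L[p, m])
                s += (k0_per_layer[m] ** 2) * Y[p, m] * alpha_db[m]
            acc += w * math.exp(-2.0 * tau * s)
        out.append(acc / L.shape[0])
    return np.array(out)


def synthetic_table(
    medium: LayeredMedium,
    partial_path,
    momentum_transfer,
    exit_radius=None,
    seed: int = 0,
) -> PhotonTable:
    """Assemble a PhotonTable from hand-specified records (test fixture)."""
    L = np.atleast_2d(np.asarray(partial_path, dtype=float))
    Y = np.atleast_2d(np.asarray(momentum_transfer, dtype=float))
    n_rec = L.shape[0]
    r = (
        np.zeros(n_rec)
        if exit_radius is None
        else np.asarray(exit_radius, dtype=float)
    )
    n = medium.prop("n")
    return PhotonTable(
        exit_radius=r,
        partial_path=L,
        momentum_transfer=Y,
        tof=L @ n / C_VAC_MM_S,
        launched=n_rec,
        medium=medium,
        config=TransportConfig(n_photons=n_rec, rng_seed=seed),
    )
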