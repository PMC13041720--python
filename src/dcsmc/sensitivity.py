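"""Relative-flow sensitivity calculus from photon histories.

The sensitivity of the normalized field autocorrelation to a fractional
flow change in layer n is s′_n(τ) = αDB,n · ∂g1/∂αDB,n(τ).  The derivative
is computed analytically from the stored photon momentum transfers:

    ∂g1/∂αDB,m(τ) = [Σ_p w_p·(−2 k0,m² τ Y_p,m)·exp(−2τ Σ_n k0,n² Y_p,n αDB,n)]
                    / G1(τ=0),

where G1(0) is independent of αDB so no quotient-rule second term arises.
The layer sensitivity for an acquisition with minimum resolvable lag
τmin = 1/f_acq is the magnitude of the lag integral

    S_n(τmin) = |∫_{τmin}^{1 s} s′_n(τ) dτ|        (composite Simpson),

and the brain sensitivity of a measurement is S_brain/(S_brain + S_scalp),
with "brain" the deepest layer and "scalp" the top layer; skull and CSF
sensitivities are computed but excluded from the ratio.

For a ToF-gated (time-resolved) measurement the photon selection carries a
Gaussian IRF weight about the gate center and g1 is normalized gate-locally;
for CW, all detected ToF are pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from ._kernels import g1_and_dg1
from .forward import FlowAbsorptionState, IRFKernel
from .medium import SimulationWavelength
from .transport import PhotonTable

__all__ = [
    "SensitivityResult",
    "select_photons",
    "dg1_dalpha",
    "integrated_sensitivity",
    "brain_sensitivity",
    "layer_sensitivities",
    "sensitivity_sweep",
]

UPPER_BOUND_S = 1.0  # lag-integration upper bound (s); decay is long dead by then


@dataclass(frozen=True)
class SensitivityResult:
    """Per-layer lag-integrated sensitivity magnitudes and the brain ratio."""

    S: np.ndarray              # per-layer |S_n|, dimensionless
    tau_min: float             # s
    context: dict = field(default_factory=dict)  # SDS annulus / ToF gate / ...
    brain_sensitivity: float = float("nan")

    @property
    def S_scalp(self) -> float:
        return float(self.S[0])

    @property
    def S_brain(self) -> float:
        return float(self.S[-1])


def select_photons(
    table: PhotonTable,
    annulus: tuple[float, float] | None = None,
    tof_gate: tuple[float, float] | str = "CW",
    irf: IRFKernel | None = None,
    gate_center: float | None = None,
):
    """Photon mask and per-photon selection weights for a measurement context.

    ``tof_gate`` is either "CW" (all ToF) or a (t1, t2) window in seconds.
    With an ``irf`` and ``gate_center``, photons are weighted by the IRF
    kernel evaluated at their ToF-bin offset from the gate bin — the exact
    per-photon equivalent of convolving the binned G1 along ToF and reading
    one gate bin.
    """
    mask = (
        table.select_annulus(*annulus)
        if annulus is not None
        else np.ones(table.n_detected, dtype=bool)
    )
    weights = np.ones(int(mask.sum()))
    tof = table.tof[mask]
    if irf is not None and gate_center is not None:
        bw = irf.bin_width
        sig = irf.sigma
        half = max(1, int(math.ceil(4.0 * sig / bw)))
        offset_bins = np.floor(tof / bw) - math.floor(gate_center / bw)
        keep = np.abs(offset_bins) <= half
        idx = np.where(mask)[0][keep]
        mask = np.zeros_like(mask)
        mask[idx] = True
        weights = np.exp(-0.5 * ((offset_bins[keep] * bw) / sig) ** 2)
    elif tof_gate != "CW":
        t1, t2 = tof_gate
        keep = (tof >= t1) & (tof < t2)
        idx = np.where(mask)[0][keep]
        mask = np.zeros_like(mask)
        mask[idx] = True
        weights = np.ones(idx.size)
    if weights.size == 0:
        raise ValueError("empty photon selection for the requested context")
    return mask, weights


def _g1_and_derivatives(
    table: PhotonTable,
    state: FlowAbsorptionState,
    wavelength: SimulationWavelength,
    lags: np.ndarray,
    mask: np.ndarray,
    sel_weights: np.ndarray,
):
    """Normalized g1(τ) and ∂g1/∂αDB,n(τ) for a weighted photon selection."""
    k0sq = table.medium.k0(wavelength) ** 2
    Q = 2.0 * table.momentum_transfer[mask] * k0sq  # (P, Nm)
    rate = Q @ state.alpha_db
    w = np.exp(-table.partial_path[mask] @ state.mua) * sel_weights
    G1, D = g1_and_dg1(w, rate, Q, lags)
    G10 = w.sum()
    return G1 / G10, D / G10


def dg1_dalpha(
    table: PhotonTable,
    state: FlowAbsorptionState,
    layer_index: int,
    wavelength: SimulationWavelength,
    lags: np.ndarray,
    annulus: tuple[float, float] | None = None,
    tof_gate: tuple[float, float] | str = "CW",
    irf: IRFKernel | None = None,
    gate_center: float | None = None,
) -> np.ndarray:
    """Analytic ∂g1/∂αDB,layer(τ) over the photon selection (per mm² s⁻¹)."""
    if not 0 <= layer_index < table.medium.n_layers:
        raise ValueError("invalid layer index")
    mask, wsel = select_photons(table, annulus, tof_gate, irf, gate_center)
    _, D = _g1_and_derivatives(table, state, wavelength, lags, mask, wsel)
    return D[layer_index]


def _simpson_magnitude(s_prime: np.ndarray, lags: np.ndarray) -> float:
    if lags.size < 3:
        return float(abs(np.trapezoid(s_prime, lags)))
    return float(abs(simpson(s_prime, x=lags)))


def integration_lags(tau_min: float, per_decade: int = 40) -> np.ndarray:
    """Log-spaced lag grid from τmin to the 1 s upper bound."""
    if not (0.0 < tau_min < UPPER_BOUND_S):
        raise ValueError("tau_min must lie in (0, 1 s)")
    n_dec = math.log10(UPPER_BOUND_S / tau_min)
    n = max(3, int(round(n_dec * per_decade)) + 1)
    return np.geomspace(tau_min, UPPER_BOUND_S, n)


def layer_sensitivities(
    table: PhotonTable,
    state: FlowAbsorptionState,
    wavelength: SimulationWavelength,
    tau_min: float,
    annulus: tuple[float, float] | None = None,
    tof_gate: tuple[float, float] | str = "CW",
    irf: IRFKernel | None = None,
    gate_center: float | None = None,
    per_decade: int = 40,
    context: dict | None = None,
) -> SensitivityResult:
    """All-layer lag-integrated sensitivities |S_n| and the brain ratio."""
    lags = integration_lags(tau_min, per_decade)
    mask, wsel = select_photons(table, annulus, tof_gate, irf, gate_center)
    _, D = _g1_and_derivatives(table, state, wavelength, lags, mask, wsel)
    S = np.array(
        [
            _simpson_magnitude(state.alpha_db[m] * D[m], lags)
            for m in range(state.n_layers)
        ]
    )
    ratio = brain_sensitivity(S[-1], S[0]) if (S[0] + S[-1]) > 0 else float("nan")
    return SensitivityResult(
        S=S, tau_min=tau_min, context=context or {}, brain_sensitivity=ratio
    )


def integrated_sensitivity(
    table: PhotonTable,
    state: FlowAbsorptionState,
    layer_index: int,
    wavelength: SimulationWavelength,
    tau_min: float,
    **kwargs,
) -> float:
    """|S_n| for one layer — see :func:`layer_sensitivities`."""
    if tau_min >= UPPER_BOUND_S:
        return 0.0
    res = layer_sensitivities(table, state, wavelength, tau_min, **kwargs)
    return float(res.S[layer_index])


def brain_sensitivity(S_brain: float, S_scalp: float) -> float:
    """S_brain / (S_brain + S_scalp)."""
    if S_brain < 0 or S_scalp < 0:
        raise ValueError("sensitivities must be nonnegative")
    denom = S_brain + S_scalp
    if denom == 0:
        raise ValueError("both sensitivities are zero: ratio undefined")
    return S_brain / denom


def sensitivity_sweep(
    table: PhotonTable,
    state: FlowAbsorptionState,
    wavelength: SimulationWavelength,
    axis: str,
    values,
    tau_min: float = 5e-6,
    annulus: tuple[float, float] | None = None,
    gate_center: float | None = None,
    irf: IRFKernel | None = None,
    annulus_halfwidth: float = 1.25,
) -> list[SensitivityResult]:
    """Sweep brain sensitivity along one axis: "sds", "tof" or "tau_min".

    For "sds", each value is an annulus center (± ``annulus_halfwidth``);
    for "tof", each value is a gate center (IRF-weighted when ``irf`` is
    given, at fixed ``annulus``); for "tau_min", the minimum lag is swept at
    a fixed context.  Annuli/gates with zero photons are skipped.
    """
    out: list[SensitivityResult] = []
    for v in values:
        try:
            if axis == "sds":
                res = layer_sensitivities(
                    table, state, wavelength, tau_min,
                    annulus=(v - annulus_halfwidth, v + annulus_halfwidth),
                    context={"sds": v, "tau_min": tau_min},
                )
            elif axis == "tof":
                res = layer_sensitivities(
                    table, state, wavelength, tau_min,
                    annulus=annulus, irf=irf, gate_center=v,
                    tof_gate=(v - 12.5e-12, v + 12.5e-12) if irf is None else "CW",
                    context={"tof": v, "tau_min": tau_min},
                )
            elif axis == "tau_min":
                res = layer_sensitivities(
                    table, state, wavelength, v,
                    annulus=annulus, irf=irf, gate_center=gate_center,
                    context={"tau_min": v},
                )
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
        except ValueError as exc:
            if "empty photon selection" in str(exc):
                continue
            raise
        out.append(res)
    return out
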