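"""Layered media, optical-property presets, and derived optical quantities.

Units are mm, s, mm⁻¹ and mm² s⁻¹ throughout the package.  A medium is an
ordered stack of plane-parallel layers, scalp side (photon launch surface)
first.  The deepest layer is treated as semi-infinite by giving it a large
finite thickness; transport additionally terminates photons on a maximum
time-of-flight, so the exact value is immaterial as long as it exceeds the
depth reachable within that limit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "C_VAC_MM_S",
    "Layer",
    "LayeredMedium",
    "SimulationWavelength",
    "wavelength_1064",
    "adult_head_preset",
    "bilayer_phantom_preset",
    "homogeneous_preset",
    "SEMI_INFINITE_MM",
]

#: Speed of light in vacuum (mm s⁻¹).
C_VAC_MM_S = 2.99792458e11

#: Thickness used to emulate a semi-infinite deepest layer (mm).
SEMI_INFINITE_MM = 150.0


@dataclass(frozen=True)
class SimulationWavelength:
    """Vacuum wavelength of the (monochromatic, coherent) source.

    Parameters
    ----------
    lambda_vac : float
        Vacuum wavelength in mm.
    c_vac : float
        Vacuum speed of light in mm s⁻¹.
    """

    lambda_vac: float
    c_vac: float = C_VAC_MM_S

    def __post_init__(self) -> None:
        if not self.lambda_vac > 0:
            raise ValueError("lambda_vac must be positive")

    def k0(self, n: float) -> float:
        """In-medium wavenumber 2π n / λ (mm⁻¹)."""
        return 2.0 * math.pi * n / self.lambda_vac


def wavelength_1064() -> SimulationWavelength:
    """The 1064 nm operating wavelength used throughout."""
    return SimulationWavelength(lambda_vac=1064e-6)


@dataclass(frozen=True)
class Layer:
    """One plane-parallel tissue layer.

    Attributes
    ----------
    label : str
        Human-readable layer name ("scalp", "skull", ...).
    thickness : float
        Layer thickness in mm (> 0).
    mua : float
        Absorption coefficient μa in mm⁻¹ (≥ 0). Absorption is never applied
        during transport (white Monte Carlo); it enters as photon weights.
    mus_prime : float
        Reduced scattering coefficient μs′ in mm⁻¹ (> 0).
    g : float
        Henyey–Greenstein anisotropy factor, 0 ≤ g < 1.
    n : float
        Refractive index (≥ 1).
    alpha_db : float
        Baseline Brownian diffusion coefficient αDB of the dynamic
        scatterers, mm² s⁻¹ (≥ 0); the blood-flow index of this layer.
    """

    label: str
    thickness: float
    mua: float
    mus_prime: float
    g: float
    n: float
    alpha_db: float

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer {self.label!r}: thickness must be > 0")
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"layer {self.label!r}: g must satisfy 0 <= g < 1")
        if not self.mus_prime > 0:
            raise ValueError(f"layer {self.label!r}: mus_prime must be > 0")
        if self.mua < 0:
            raise ValueError(f"layer {self.label!r}: mua must be >= 0")
        if self.n < 1:
            raise ValueError(f"layer {self.label!r}: n must be >= 1")
        if self.alpha_db < 0:
            raise ValueError(f"layer {self.label!r}: alpha_db must be >= 0")

    @property
    def mus(self) -> float:
        """Scattering coefficient μs = μs′ / (1 − g), mm⁻¹ (similarity relation)."""
        return self.mus_prime / (1.0 - self.g)


@dataclass(frozen=True)
class LayeredMedium:
    """An ordered stack of layers with an ambient half-space above the top.

    ``layers[0]`` is the launch-side (scalp) layer.  ``ambient_n`` is the
    refractive index above the top surface (1.0 = air, bare-fiber probe).
    """

    layers: tuple[Layer, ...]
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("medium needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def boundaries(self) -> np.ndarray:
        """Depths of the layer interfaces, z[0]=0 … z[N] (mm), strictly increasing."""
        return np.concatenate(
            [[0.0], np.cumsum([la.thickness for la in self.layers])]
        )

    def prop(self, name: str) -> np.ndarray:
        """Per-layer array of one Layer attribute/property."""
        return np.array([getattr(la, name) for la in self.layers], dtype=float)

    def k0(self, wavelength: SimulationWavelength) -> np.ndarray:
        """Per-layer in-medium wavenumbers (mm⁻¹)."""
        return np.array([wavelength.k0(la.n) for la in self.layers])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ambient_n": self.ambient_n,
            "layers": [
                {
                    "label": la.label,
                    "thickness": la.thickness,
                    "mua": la.mua,
                    "mus_prime": la.mus_prime,
                    "g": la.g,
                    "n": la.n,
                    "alpha_db": la.alpha_db,
                }
                for la in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredMedium":
        return cls(
            layers=tuple(Layer(**ld) for ld in d["layers"]),
            ambient_n=float(d.get("ambient_n", 1.0)),
        )

    def fingerprint(self) -> str:
        """Stable hash of all medium parameters (for photon-table provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def adult_head_preset(
    skull_thickness: float = 6.0,
    scalp_alpha_db: float = 1e-6,
    brain_alpha_db: float = 5e-6,
    scalp_mua: float = 0.012,
    brain_mua: float = 0.017,
    skull_alpha_db: float = 2e-8,
    mus_prime: float = 0.84,
) -> LayeredMedium:
    """Four-layer adult head: scalp / skull / CSF / brain.

    Default optical properties at 1064 nm.  The distance to brain is
    4 mm (scalp) + ``skull_thickness`` + 2 mm (CSF); 12 mm for the median
    adult forehead.  Skull thickness and layer αDB values are the knobs used
    for population depth sweeps and baseline-flow sweeps.
    """
    return LayeredMedium(
        layers=(
            Layer("scalp", 4.0, scalp_mua, mus_prime, 0.9, 1.4, scalp_alpha_db),
            Layer("skull", skull_thickness, 0.013, mus_prime, 0.9, 1.4, skull_alpha_db),
            Layer("csf", 2.0, 0.012, 0.009, 0.9, 1.33, 5e-8),
            Layer("brain", SEMI_INFINITE_MM, brain_mua, mus_prime, 0.9, 1.4, brain_alpha_db),
        ),
        ambient_n=1.0,
    )


def bilayer_phantom_preset(
    bottom_mus_prime: float,
    alpha_db: float = 1e-5,
    top_thickness: float = 10.0,
) -> LayeredMedium:
    """Two-layer intralipid phantom: a 10 mm top layer over a deep bottom layer.

    The top layer has μs′ = 0.55 mm⁻¹; the bottom layer μs′ is set by the
    intralipid concentration (measured presets: 0.55, 1.0, 1.8, 2.6 mm⁻¹).
    Both layers share water-like absorption (μa = 0.015 mm⁻¹), n = 1.33 and
    g = 0.53 (intralipid at 1064 nm).  A higher bottom μs′ mimics a faster
    lower-layer decorrelation, analogous to brain under scalp.  The thin
    separating film of the physical phantom is neglected.  ``alpha_db``
    applies to both layers (Brownian motion of the intralipid droplets).
    """
    if not bottom_mus_prime > 0:
        raise ValueError("bottom_mus_prime must be positive")
    return LayeredMedium(
        layers=(
            Layer("top", top_thickness, 0.015, 0.55, 0.53, 1.33, alpha_db),
            Layer("bottom", SEMI_INFINITE_MM, 0.015, bottom_mus_prime, 0.53, 1.33, alpha_db),
        ),
        ambient_n=1.0,
    )


def homogeneous_preset(
    mus_prime: float = 0.84,
    g: float = 0.9,
    n: float = 1.4,
    mua: float = 0.012,
    alpha_db: float = 1e-6,
) -> LayeredMedium:
    """Semi-infinite homogeneous reference medium (defaults: scalp optics)."""
    return LayeredMedium(
        layers=(Layer("bulk", SEMI_INFINITE_MM, mua, mus_prime, g, n, alpha_db),),
        ambient_n=1.0,
    )
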