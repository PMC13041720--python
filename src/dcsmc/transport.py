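"""Scattering-only Monte Carlo photon transport through a layered slab.

One transport run produces a :class:`PhotonTable` — the columnar record of
per-layer partial pathlengths and dimensionless momentum transfers for every
detected photon.  Absorption is *not* applied during transport (white Monte
Carlo): it enters later as per-photon weights, so a single table serves every
absorption and flow state in a pulsatile replay.

Detection uses the full top surface with no numerical-aperture cut; photons
are binned by exit radius into annuli downstream, exploiting the lateral
symmetry of the slab to multiply the effective detector area.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from ._kernels import transport_chunk
from .medium import LayeredMedium, SimulationWavelength, C_VAC_MM_S

__all__ = [
    "TransportConfig",
    "PhotonTable",
    "simulate",
    "tof_of",
    "save_table",
    "load_table",
    "annulus_summary",
]

_CHUNK = 200_000  # photons per kernel invocation (bounds scratch memory)


@dataclass(frozen=True)
class TransportConfig:
    """Configuration of one transport run.

    ``max_tof`` (s) and ``max_radius`` (mm) are termination criteria; the
    defaults cover analyses out to 1.5 ns with margin.  ``annulus_edges``
    are metadata describing the detection rings intended for downstream
    binning; every photon exiting within ``max_radius`` is recorded
    regardless, so the edges can be revised after the fact.
    """

    n_photons: int
    rng_seed: int
    max_tof: float = 5e-9
    max_radius: float = 120.0
    annulus_edges: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.arange(5.0, 52.6, 2.5))
    )

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not self.max_tof > 0:
            raise ValueError("max_tof must be > 0")
        edges = np.asarray(self.annulus_edges, dtype=float)
        if edges.size and (np.any(np.diff(edges) <= 0) or edges[0] < 0):
            raise ValueError("annulus_edges must be strictly increasing and >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["annulus_edges"] = list(self.annulus_edges)
        return d


@dataclass
class PhotonTable:
    """Columnar record of detected photons from one transport run.

    Attributes
    ----------
    exit_radius : (N,) float array, mm
    partial_path : (N, Nm) float array — per-layer pathlengths L_pn, mm
    momentum_transfer : (N, Nm) float array — per-layer Σ(1−cosθ), Y_pn
    tof : (N,) float array, s — Σ_n L_pn n_n / c
    launched : int — photons launched (detected ≤ launched)
    medium : LayeredMedium — the medium simulated (snapshot)
    config : TransportConfig
    """

    exit_radius: np.ndarray
    partial_path: np.ndarray
    momentum_transfer: np.ndarray
    tof: np.ndarray
    launched: int
    medium: LayeredMedium
    config: TransportConfig

    @property
    def n_detected(self) -> int:
        return self.exit_radius.shape[0]

    @property
    def fingerprint(self) -> str:
        return self.medium.fingerprint()

    def select_annulus(self, r_in: float, r_out: float) -> np.ndarray:
        """Boolean mask of photons with exit radius in [r_in, r_out)."""
        return (self.exit_radius >= r_in) & (self.exit_radius < r_out)


def simulate(
    medium: LayeredMedium,
    wavelength: SimulationWavelength,
    cfg: TransportConfig,
) -> PhotonTable:
    """Run the transport and return the photon lookup table.

    A pencil beam is launched normally at the origin of the top surface.
    Deterministic for a fixed ``cfg.rng_seed``.  The wavelength does not
    enter the transport itself (scattering-only, geometric paths); it is
    carried for provenance.
    """
    if medium.n_layers < 1:
        raise ValueError("empty medium")
    mus = medium.prop("mus")
    if mus[0] * medium.layers[0].thickness < 1e-2:
        warnings.warn(
            "top layer is effectively non-scattering: no diffuse detection "
            "is possible at SDS > 0",
            stacklevel=2,
        )
    zb = medium.boundaries
    g = medium.prop("g")
    n_layer = medium.prop("n")
    nm = medium.n_layers

    rs, Ls, Ys, tofs = [], [], [], []
    remaining = cfg.n_photons
    chunk_no = 0
    while remaining > 0:
        this = min(_CHUNK, remaining)
        out_r = np.empty(this)
        out_L = np.empty((this, nm))
        out_Y = np.empty((this, nm))
        out_tof = np.empty(this)
        # distinct, reproducible sub-seed per chunk
        sub_seed = (cfg.rng_seed + 1_000_003 * chunk_no) % (2**32 - 1)
        count = transport_chunk(
            this, sub_seed, zb, mus, g, n_layer, medium.ambient_n,
            cfg.max_tof, cfg.max_radius, C_VAC_MM_S,
            out_r, out_L, out_Y, out_tof,
        )
        rs.append(out_r[:count].copy())
        Ls.append(out_L[:count].copy())
        Ys.append(out_Y[:count].copy())
        tofs.append(out_tof[:count].copy())
        remaining -= this
        chunk_no += 1

    return PhotonTable(
        exit_radius=np.concatenate(rs) if rs else np.empty(0),
        partial_path=np.concatenate(Ls) if Ls else np.empty((0, nm)),
        momentum_transfer=np.concatenate(Ys) if Ys else np.empty((0, nm)),
        tof=np.concatenate(tofs) if tofs else np.empty(0),
        launched=cfg.n_photons,
        medium=medium,
        config=cfg,
    )


def tof_of(partial_path: np.ndarray, medium: LayeredMedium) -> float | np.ndarray:
    """Time of flight from per-layer optical pathlengths: Σ_n L_n·n_n / c.

    ``partial_path`` may be one record (Nm,) or a stack (N, Nm).
    """
    L = np.asarray(partial_path, dtype=float)
    n = medium.prop("n")
    if L.shape[-1] != medium.n_layers:
        raise ValueError(
            f"record has {L.shape[-1]} layers, medium has {medium.n_layers}"
        )
    return L @ n / C_VAC_MM_S


# ---------------------------------------------------------------------------
# Persistence (HDF5)
# ---------------------------------------------------------------------------


def save_table(table: PhotonTable, path) -> None:
    """Persist a PhotonTable losslessly to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("exit_radius", data=table.exit_radius)
        f.create_dataset("partial_path", data=table.partial_path)
        f.create_dataset("momentum_transfer", data=table.momentum_transfer)
        f.create_dataset("tof", data=table.tof)
        f.attrs["launched"] = table.launched
        f.attrs["seed"] = table.config.rng_seed
        f.attrs["fingerprint"] = table.fingerprint
        f.attrs["medium_json"] = json.dumps(table.medium.to_dict())
        f.attrs["config_json"] = json.dumps(table.config.to_dict())


def load_table(path, expected_medium: LayeredMedium | None = None) -> PhotonTable:
    """Load a PhotonTable; warn (but return) on a medium-fingerprint mismatch."""
    try:
        with h5py.File(path, "r") as f:
            required = ("exit_radius", "partial_path", "momentum_transfer", "tof")
            if any(k not in f for k in required):
                raise ValueError(f"{path}: not a photon table (missing datasets)")
            medium = LayeredMedium.from_dict(json.loads(f.attrs["medium_json"]))
            cfg_d = json.loads(f.attrs["config_json"])
            cfg_d["annulus_edges"] = tuple(cfg_d["annulus_edges"])
            cfg = TransportConfig(**cfg_d)
            table = PhotonTable(
                exit_radius=f["exit_radius"][:],
                partial_path=f["partial_path"][:],
                momentum_transfer=f["momentum_transfer"][:],
                tof=f["tof"][:],
                launched=int(f.attrs["launched"]),
                medium=medium,
                config=cfg,
            )
    except OSError as exc:
        raise ValueError(f"{path}: unreadable or truncated photon table") from exc
    if expected_medium is not None and (
        expected_medium.fingerprint() != table.fingerprint
    ):
        warnings.warn(
            f"photon table medium fingerprint {table.fingerprint} does not "
            f"match the expected medium {expected_medium.fingerprint()}",
            stacklevel=2,
        )
    return table


def annulus_summary(table: PhotonTable) -> "pandas.DataFrame":  # noqa: F821
    """Per-annulus detected counts and mean ToF (inspection/CSV export)."""
    import pandas as pd

    edges = np.asarray(table.config.annulus_edges)
    rows = []
    for r_in, r_out in zip(edges[:-1], edges[1:]):
        m = table.select_annulus(r_in, r_out)
        rows.append(
            {
                "r_in_mm": r_in,
                "r_out_mm": r_out,
                "n_photons": int(m.sum()),
                "mean_tof_s": float(table.tof[m].mean()) if m.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
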