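"""Scenario configuration, presets, caching and reproducibility plumbing.

A scenario is one YAML document that fully determines a run: a medium
(preset name or inline layer list), a transport configuration, and an
analysis request.  The expensive transport step is cached on the hash of
(medium, transport config, seed), mirroring the single-lookup-table design:
forward, sensitivity and pulsatile analyses all replay the same table.

Config schema (YAML)::

    medium: adult_head_median            # preset name, or {ambient_n, layers: [...]}
    transport: {n_photons: 1000000, rng_seed: 1, max_tof: 2.0e-9, max_radius: 60}
    analysis:
      kind: crossing                     # forward|sensitivity|pulsatile|crossing
      ...kind-specific parameters...
    out_dir: runs/demo
    seed: 1
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .forward import (
    FlowAbsorptionState,
    IRFKernel,
    LagGrid,
    ToFGrid,
    g1_surface,
)
from .medium import (
    LayeredMedium,
    adult_head_preset,
    bilayer_phantom_preset,
    homogeneous_preset,
    wavelength_1064,
)
from .pulsatile import (
    CWConfig,
    SCOSConfig,
    TDConfig,
    WaveformSpec,
    cw_sds_crossing,
    evaluate_recovery,
    make_waveform,
    scos_sds_crossing,
    simulate_timeseries,
    td_tof_crossing,
)
from .sensitivity import sensitivity_sweep
from .transport import TransportConfig, load_table, save_table, simulate

__all__ = [
    "MEDIA_PRESETS",
    "SCENARIO_PRESETS",
    "resolve_medium",
    "list_presets",
    "load_config",
    "run_scenario",
]


def _depth_preset(depth: float):
    return lambda: adult_head_preset(skull_thickness=depth - 6.0)


MEDIA_PRESETS: dict = {
    "adult_head_median": adult_head_preset,
    "homogeneous_reference": homogeneous_preset,
    "intralipid_bilayer_055": lambda: bilayer_phantom_preset(0.55),
    "intralipid_bilayer_10": lambda: bilayer_phantom_preset(1.0),
    "intralipid_bilayer_18": lambda: bilayer_phantom_preset(1.8),
    "intralipid_bilayer_26": lambda: bilayer_phantom_preset(2.6),
}
for _d in range(9, 19):
    MEDIA_PRESETS[f"adult_head_depth_{_d}"] = _depth_preset(float(_d))


#: Ready-made scenario configurations (seed/out_dir supplied at run time).
SCENARIO_PRESETS: dict = {
    "td_tof_sweep": {
        "medium": "adult_head_median",
        "transport": {"n_photons": 2_000_000, "max_tof": 1.9e-9, "max_radius": 60.0},
        "analysis": {"kind": "crossing", "modality": "TD"},
    },
    "cw_sds_sweep": {
        "medium": "adult_head_median",
        "transport": {"n_photons": 4_000_000, "max_tof": 5e-9, "max_radius": 80.0},
        "analysis": {"kind": "crossing", "modality": "CW-DCS"},
    },
    "scos_sds_sweep": {
        "medium": "adult_head_median",
        "transport": {"n_photons": 4_000_000, "max_tof": 5e-9, "max_radius": 80.0},
        "analysis": {"kind": "crossing", "modality": "SCOS"},
    },
    "lag_sweep": {
        "medium": "adult_head_median",
        "transport": {"n_photons": 2_000_000, "max_tof": 5e-9, "max_radius": 80.0},
        "analysis": {
            "kind": "sensitivity",
            "axis": "tau_min",
            "values": [1e-7, 1e-6, 1e-5, 1e-4, 1e-3],
            "sds": 30.0,
        },
    },
    "sensitivity_tof_sweep": {
        "medium": "adult_head_median",
        "transport": {"n_photons": 2_000_000, "max_tof": 1.9e-9, "max_radius": 60.0},
        "analysis": {
            "kind": "sensitivity",
            "axis": "tof",
            "values": [round(0.4e-9 + 0.1e-9 * i, 13) for i in range(11)],
            "sds": 10.0,
            "tau_min": 5e-6,
        },
    },
    "phantom_bilayer": {
        "medium": "intralipid_bilayer_26",
        "transport": {"n_photons": 1_000_000, "max_tof": 2.5e-9, "max_radius": 60.0},
        "analysis": {"kind": "forward", "sds": 10.0},
    },
}


def resolve_medium(spec) -> LayeredMedium:
    """A medium from a preset name or an inline dict."""
    if isinstance(spec, str):
        try:
            return MEDIA_PRESETS[spec]()
        except KeyError:
            raise ValueError(
                f"medium: unknown preset {spec!r} "
                f"(known: {', '.join(sorted(MEDIA_PRESETS))})"
            ) from None
    if isinstance(spec, dict):
        try:
            return LayeredMedium.from_dict(spec)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"medium: invalid inline medium spec: {exc}") from exc
    raise ValueError("medium: must be a preset name or a mapping")


def list_presets() -> dict:
    """Names and one-line descriptions of media and scenario presets."""
    media = {}
    for name, factory in MEDIA_PRESETS.items():
        med = factory()
        depth = float(med.boundaries[-2]) if med.n_layers > 1 else float("inf")
        media[name] = (
            f"{med.n_layers} layers"
            + (f", distance-to-brain {depth:g} mm" if name.startswith("adult") else "")
        )
    scenarios = {name: cfg["analysis"]["kind"] for name, cfg in SCENARIO_PRESETS.items()}
    return {"media": media, "scenarios": scenarios}


def load_config(path) -> dict:
    """Load and validate a scenario config; errors name the offending field."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for key in ("medium", "transport", "analysis"):
        if key not in cfg:
            raise ValueError(f"{path}: missing required field {key!r}")
    resolve_medium(cfg["medium"])  # raises with field path
    if "kind" not in cfg["analysis"]:
        raise ValueError(f"{path}: analysis.kind is required")
    if cfg["analysis"]["kind"] not in ("forward", "sensitivity", "pulsatile", "crossing"):
        raise ValueError(f"{path}: analysis.kind {cfg['analysis']['kind']!r} unknown")
    return cfg


def _config_hash(medium: LayeredMedium, tcfg: TransportConfig) -> str:
    payload = json.dumps(
        {"medium": medium.to_dict(), "transport": tcfg.to_dict()}, sort_keys=True
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def get_or_simulate_table(medium, wavelength, tcfg, cache_dir: Path, log):
    """Load a cached photon table for this (medium, transport, seed) hash or
    run the transport and cache it."""
    cache_dir.mkdir(parents=True, exist_ok=True)
    h = _config_hash(medium, tcfg)
    path = cache_dir / f"table_{h}.h5"
    if path.exists():
        try:
            table = load_table(path, expected_medium=medium)
            log(f"cache hit: {path.name}")
            return table, True, h
        except ValueError:
            log(f"cache entry {path.name} unreadable; re-simulating")
    t0 = time.time()
    table = simulate(medium, wavelength, tcfg)
    save_table(table, path)
    log(
        f"transport: {tcfg.n_photons} photons, {table.n_detected} detected "
        f"({time.time() - t0:.1f} s) -> {path.name}"
    )
    return table, False, h


def _run_analysis(cfg, table, medium, wavelength, series_spec, out_dir, log):
    import pandas as pd

    ana = cfg["analysis"]
    kind = ana["kind"]
    results: dict = {"kind": kind}
    if kind == "forward":
        state = FlowAbsorptionState.from_medium(medium)
        sds = float(ana.get("sds", 10.0))
        surf = g1_surface(
            table, state, ToFGrid.uniform(), LagGrid.log(), wavelength,
            annulus=(sds - 1.0, sds + 1.0),
        )
        g1 = surf.g1()
        rows = []
        for b in np.where(surf.occupied)[0]:
            for j, tau in enumerate(surf.lag_grid.lags):
                rows.append(
                    (surf.tof_grid.centers[b], tau, surf.G1[b, j], g1[b, j])
                )
        pd.DataFrame(rows, columns=["tof_s", "lag_s", "G1", "g1"]).to_csv(
            out_dir / "g1_surface.csv", index=False
        )
        results["n_occupied_bins"] = int(surf.occupied.sum())
    elif kind == "sensitivity":
        state = FlowAbsorptionState.from_medium(medium)
        sds = float(ana.get("sds", 10.0))
        irf = IRFKernel(float(ana.get("irf_fwhm", 125e-12)), 25e-12)
        sweep = sensitivity_sweep(
            table, state, wavelength,
            axis=ana["axis"], values=ana["values"],
            tau_min=float(ana.get("tau_min", 5e-6)),
            annulus=(sds - 1.25, sds + 1.25),
            gate_center=ana.get("gate_center"),
            irf=irf if ana["axis"] == "tof" else None,
        )
        df = pd.DataFrame(
            [
                {
                    "axis_value": r.context.get(ana["axis"].replace("tau_min", "tau_min")),
                    "S_scalp": r.S_scalp,
                    "S_brain": r.S_brain,
                    "brain_sensitivity": r.brain_sensitivity,
                }
                for r in sweep
            ]
        )
        df.to_csv(out_dir / "sensitivity.csv", index=False)
        results["n_points"] = len(df)
    elif kind in ("pulsatile", "crossing"):
        series = make_waveform(series_spec, medium)
        modality = ana.get("modality", "TD")
        if kind == "pulsatile":
            cfg_map = {"TD": TDConfig, "CW-DCS": CWConfig, "SCOS": SCOSConfig}
            mcfg = cfg_map[modality](**ana.get("params", {}))
            rec = simulate_timeseries(table, series, mcfg, wavelength)
            r_cbf, r_sbf = evaluate_recovery(rec, series)
            pd.DataFrame(
                {"time_s": series.time, "rbfi": rec.rbfi,
                 "rcbf": series.rcbf, "rsbf": series.rsbf}
            ).to_csv(out_dir / "rbfi.csv", index=False)
            results.update(
                modality=modality, r_cbf=r_cbf, r_sbf=r_sbf, context=rec.context
            )
        else:
            fn = {
                "TD": td_tof_crossing,
                "CW-DCS": cw_sds_crossing,
                "SCOS": scos_sds_crossing,
            }[modality]
            cr = fn(table, series, wavelength)
            pd.DataFrame(
                {"axis_value": cr.axis_values, "r_cbf": cr.r_cbf, "r_sbf": cr.r_sbf}
            ).to_csv(out_dir / "crossing_curve.csv", index=False)
            results.update(
                modality=modality,
                crossing=None if not cr.valid else cr.crossing,
                valid=cr.valid,
                boundary_direction=cr.boundary_direction,
            )
    log(f"analysis {kind}: done")
    return results


def run_scenario(config, out_dir=None, seed: int | None = None) -> dict:
    """Execute one scenario end to end; returns the manifest dict.

    ``config`` is a path to a YAML file, a preset name, or a config dict.
    Outputs (CSV curves, JSON manifest, run log, cached photon table) land
    in ``out_dir`` (default: the config's ``out_dir`` or ``./runs``).
    """
    if isinstance(config, (str, Path)) and str(config) in SCENARIO_PRESETS:
        cfg = dict(SCENARIO_PRESETS[str(config)])
    elif isinstance(config, dict):
        cfg = dict(config)
    else:
        cfg = load_config(config)

    seed = int(seed if seed is not None else cfg.get("seed", 1))
    out_dir = Path(out_dir or cfg.get("out_dir", "runs"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log_lines.append(line)

    medium = resolve_medium(cfg["medium"])
    wavelength = wavelength_1064()
    t = dict(cfg["transport"])
    t.setdefault("rng_seed", seed)
    tcfg = TransportConfig(**{k: (tuple(v) if k == "annulus_edges" else v)
                              for k, v in t.items()})
    log(f"scenario seed={seed} medium={medium.fingerprint()}")

    table, cache_hit, chash = get_or_simulate_table(
        medium, wavelength, tcfg, out_dir / "cache", log
    )
    spec_kwargs = cfg.get("waveform", {})
    series_spec = WaveformSpec(**spec_kwargs)
    results = _run_analysis(cfg, table, medium, wavelength, series_spec, out_dir, log)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "medium_fingerprint": medium.fingerprint(),
        "config_hash": chash,
        "cache_hit": cache_hit,
        "n_detected": table.n_detected,
        "results": results,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
    with open(out_dir / "run.log", "w") as f:
        f.write("\n".join(log_lines) + "\n")
    return manifest
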