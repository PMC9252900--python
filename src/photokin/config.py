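"""Structured-text (YAML) configuration for simulation and CLI runs.

A simulation config names a scheme (``default_pfr`` or an explicit mapping),
a band table (``default_vis`` / ``default_ir`` or a list of band mappings),
grids, IRF, noise (seed mandatory for simulation runs) and optional
oscillations. Units are explicit in the field names: fs, ps, cm-1, mOD.
"""

from __future__ import annotations

import numpy as np
import yaml

from .kinetics import CompartmentScheme, InstrumentResponse
from .simulate import (
    NoiseSpec,
    OscillationComponent,
    SpectralBand,
    default_bands_ir,
    default_bands_vis,
    default_oscillations,
    default_scheme_pfr,
)

__all__ = [
    "load_config",
    "scheme_from_config",
    "bands_from_config",
    "grid_from_config",
    "irf_from_config",
    "noise_from_config",
    "oscillations_from_config",
]


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def scheme_from_config(spec) -> CompartmentScheme:
    if spec in (None, "default_pfr"):
        return default_scheme_pfr()
    if isinstance(spec, CompartmentScheme):
        return spec
    return CompartmentScheme(
        states=spec["states"],
        lifetimes={k: float(v) for k, v in spec.get("lifetimes_ps", {}).items()},
        branching=spec.get("branching", {}),
        initial_population={k: float(v)
                            for k, v in spec["initial_population"].items()},
        ground_state=spec.get("ground_state"),
    )


def bands_from_config(spec) -> list:
    if spec in (None, "default_vis"):
        return default_bands_vis()
    if spec == "default_ir":
        return default_bands_ir()
    bands = []
    for b in spec:
        bands.append(SpectralBand(
            label=b.get("label", "band"),
            center=float(b.get("center_cm", b.get("center", 0.0))),
            fwhm=float(b.get("fwhm_cm", b.get("fwhm", 1.0))),
            amplitude=float(b.get("amplitude_mOD", b.get("amplitude", 0.0))),
            shape=b.get("shape", "gaussian"),
            tdm_angle=b.get("tdm_angle_deg", b.get("tdm_angle")),
            compartment=b.get("compartment", "S1"),
            low=b.get("low_cm", b.get("low")),
            high=b.get("high_cm", b.get("high")),
            edge_width=float(b.get("edge_width_cm", b.get("edge_width", 10.0))),
        ))
    return bands


def grid_from_config(spec, default=None) -> np.ndarray:
    if spec is None:
        if default is None:
            raise ValueError("grid missing from config")
        return np.asarray(default, dtype=float)
    if isinstance(spec, dict):
        if spec.get("spacing") == "log":
            return np.geomspace(float(spec["start"]), float(spec["stop"]),
                                int(spec["n"]))
        if "step" in spec:
            return np.arange(float(spec["start"]),
                             float(spec["stop"]) + float(spec["step"]) / 2,
                             float(spec["step"]))
        return np.linspace(float(spec["start"]), float(spec["stop"]),
                           int(spec["n"]))
    return np.asarray(spec, dtype=float)


def irf_from_config(spec) -> InstrumentResponse:
    if spec is None:
        return InstrumentResponse(fwhm=60.0, t0=0.0)
    return InstrumentResponse(fwhm=float(spec.get("fwhm_fs", spec.get("fwhm", 60.0))),
                              t0=float(spec.get("t0_fs", spec.get("t0", 0.0))))


def noise_from_config(spec, seed=None) -> NoiseSpec | None:
    if spec is None and seed is None:
        return None
    spec = spec or {}
    if seed is None:
        if "seed" not in spec:
            raise ValueError("simulation config must carry a seed")
        seed = spec["seed"]
    return NoiseSpec(sigma_abs=float(spec.get("sigma_abs_mOD",
                                              spec.get("sigma_abs", 0.0))),
                     seed=int(seed))


def oscillations_from_config(spec) -> list:
    if spec in (None, [], False):
        return []
    if spec == "default":
        return default_oscillations()
    return [OscillationComponent(
        frequency=float(o.get("frequency_cm", o.get("frequency"))),
        damping_time=float(o.get("damping_fs", o.get("damping_time"))),
        phase=float(o.get("phase_rad", o.get("phase", 0.0))),
        amplitude=float(o.get("amplitude_mOD", o.get("amplitude", 1.0))),
    ) for o in spec]
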