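"""Plain-text serialisation: CSV tables, ESRI ASCII grid rasters, YAML config."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .experiment import ExperimentConfig
from .landscape import Landscape
from .succession import SuccessionConfig

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape_layers",
    "load_config",
    "dump_config",
]


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    cellsize: float = 100.0,
    nodata: float = -9999,
) -> None:
    """Write one 2-D layer as an ESRI ASCII grid (single band, text)."""
    a = np.asarray(array)
    if a.ndim != 2:
        raise ValueError("ASCII grid layers must be 2-D")
    header = (
        f"ncols {a.shape[1]}\n"
        f"nrows {a.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(a.dtype, np.integer) or a.dtype == bool else "%.6g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, a.astype(int) if a.dtype == bool else a, fmt=fmt)


def read_ascii_grid(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        for _ in range(6):
            fh.readline()
        return np.loadtxt(fh)


def write_landscape_layers(landscape: Landscape, out_dir: str | Path) -> list[Path]:
    """One ASCII grid file per landscape layer; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layers = {
        "active": landscape.active,
        "stand_id": landscape.stand_id,
        "ecoregion_id": landscape.ecoregion_id,
        "fire_region_id": landscape.fire_region_id,
        "protected": landscape.protected,
        "protected_patch_id": landscape.protected_patch_id,
        "zone": landscape.zone,
    }
    paths = []
    for name, layer in layers.items():
        p = out / f"{name}.asc"
        write_ascii_grid(p, layer)
        paths.append(p)
    return paths


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML key-value file.

    Keys mirror the dataclass fields; a nested ``succession`` mapping fills
    the SuccessionConfig.  Unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    succ_raw = raw.pop("succession", {})
    known = set(ExperimentConfig.__dataclass_fields__) - {"succession"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    succ_known = set(SuccessionConfig.__dataclass_fields__)
    unknown = set(succ_raw) - succ_known
    if unknown:
        raise ValueError(f"unknown succession config keys: {sorted(unknown)}")
    if "shade_thresholds" in succ_raw:
        succ_raw["shade_thresholds"] = tuple(succ_raw["shade_thresholds"])
    return ExperimentConfig(succession=SuccessionConfig(**succ_raw), **raw)


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    data = {
        k: getattr(config, k)
        for k in ExperimentConfig.__dataclass_fields__
        if k != "succession"
    }
    data["succession"] = {
        k: (list(v) if isinstance(v := getattr(config.succession, k), tuple) else v)
        for k in SuccessionConfig.__dataclass_fields__
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
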