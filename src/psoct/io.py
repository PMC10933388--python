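"""Readers and writers: YAML phantom configs, TIFF volumes, JSON sidecars, CSVs.

Conventions
-----------
* A :class:`~psoct.phantom.PhantomSpec` round-trips through a YAML file with a
  nested layer list.
* A tomogram persists as one 32-bit float multi-page TIFF per channel (page 0
  real part, page 1 imaginary part) plus a JSON sidecar holding wavelength,
  axial pixel pitch, seed and a hash of the generating spec.
* Polarization maps persist as one 32-bit float TIFF per parameter plus a JSON
  sidecar echoing the processing configuration, readable back losslessly at
  float32 precision.
* Tables (profiles, metrics, group comparisons) are plain CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import DualChannelTomogram, LayerSpec, PhantomSpec
from .polarization import PolarizationMaps

__all__ = [
    "save_spec",
    "load_spec",
    "spec_hash",
    "save_tomogram",
    "load_tomogram",
    "save_maps",
    "load_maps",
    "save_profiles_csv",
    "save_metrics_csv",
]


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["layers"] = [dataclasses.asdict(l) for l in spec.layers]
    return d


def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_spec_to_dict(spec), sort_keys=True))


def load_spec(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    layers = tuple(LayerSpec(**ld) for ld in d.pop("layers"))
    return PhantomSpec(layers=layers, **d)


def spec_hash(spec: PhantomSpec) -> str:
    """Stable content hash of a phantom spec (for provenance sidecars)."""
    blob = yaml.safe_dump(_spec_to_dict(spec), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_complex_tiff(path: Path, a: np.ndarray) -> None:
    stack = np.stack([np.real(a), np.imag(a)]).astype(np.float32)
    tifffile.imwrite(path, stack)


def _read_complex_tiff(path: Path) -> np.ndarray:
    stack = tifffile.imread(path)
    return stack[0].astype(np.float64) + 1j * stack[1].astype(np.float64)


def save_tomogram(
    tom: DualChannelTomogram,
    outdir: str | Path,
    stem: str = "tomogram",
    extra_meta: dict | None = None,
) -> dict[str, Path]:
    """Write channel TIFFs + JSON sidecar; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ch0": outdir / f"{stem}_ch0.tif",
        "ch1": outdir / f"{stem}_ch1.tif",
        "sidecar": outdir / f"{stem}.json",
    }
    _write_complex_tiff(paths["ch0"], tom.a0)
    _write_complex_tiff(paths["ch1"], tom.a1)
    sidecar = {
        "format": "psoct-tomogram-v1",
        "wavelength_um": tom.wavelength_um,
        "axial_px_um": tom.axial_px_um,
        "shape": list(tom.shape),
        "meta": _jsonable(tom.meta),
    }
    if extra_meta:
        sidecar.update(_jsonable(extra_meta))
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def load_tomogram(outdir: str | Path, stem: str = "tomogram") -> DualChannelTomogram:
    outdir = Path(outdir)
    sidecar_path = outdir / f"{stem}.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing tomogram sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    a0 = _read_complex_tiff(outdir / f"{stem}_ch0.tif")
    a1 = _read_complex_tiff(outdir / f"{stem}_ch1.tif")
    return DualChannelTomogram(
        a0=a0,
        a1=a1,
        axial_px_um=sidecar["axial_px_um"],
        wavelength_um=sidecar["wavelength_um"],
        meta=sidecar.get("meta", {}),
    )


def save_maps(maps: PolarizationMaps, outdir: str | Path) -> dict[str, Path]:
    """One float32 TIFF per parameter map + a JSON sidecar with the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in maps.as_dict().items():
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[name] = p
    sidecar = {
        "format": "psoct-maps-v1",
        "wavelength_um": maps.wavelength_um,
        "axial_px_um": maps.axial_px_um,
        "units": {
            "retardation": "rad",
            "optic_axis": "rad",
            "dopu": "",
            "local_birefringence": "",
        },
        "meta": _jsonable(maps.meta),
    }
    sp = outdir / "maps.json"
    sp.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = sp
    return paths


def load_maps(outdir: str | Path) -> PolarizationMaps:
    outdir = Path(outdir)
    sidecar_path = outdir / "maps.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing maps sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    arrays = {}
    for name in ("retardation", "optic_axis", "dopu", "local_birefringence"):
        p = outdir / f"{name}.tif"
        if not p.exists():
            raise FileNotFoundError(f"missing map file: {p}")
        arrays[name] = tifffile.imread(p)
    return PolarizationMaps(
        axial_px_um=sidecar["axial_px_um"],
        wavelength_um=sidecar["wavelength_um"],
        meta=sidecar.get("meta", {}),
        **arrays,
    )


def save_profiles_csv(profiles, path: str | Path) -> None:
    """Write DepthProfile objects as one tidy CSV."""
    frames = []
    for prof in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "parameter": prof.parameter_name,
                    "depth_um": prof.depth_um,
                    "mean": prof.mean,
                    "std": prof.std,
                    "n_lateral": prof.n_lateral,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_metrics_csv(rows: pd.DataFrame | list[dict], path: str | Path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
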