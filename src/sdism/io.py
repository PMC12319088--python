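"""File formats, run configuration and the canonical fixture generator.

Raw stacks travel as multi-page TIFF plus a JSON sidecar carrying the
acquisition metadata (per-frame commanded offsets, mode, optical config,
seed, noise parameters) — adapting real microscope exports only requires
writing one JSON file next to the TIFF.  Disk layouts and shift tables are
CSV; reports and provenance are JSON; run configuration is YAML with a
strict schema (unknown keys rejected).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .dmd import multifocal_sequence
from .optics import InvalidParameterError, OpticalConfig
from .phantoms import Phantom3D, bead_phantom, filament_phantom, point_grid_phantom, two_layer_phantom
from .simulate import RawStack, simulate_stack

__all__ = [
    "read_stack",
    "write_stack",
    "write_psf",
    "write_layout_csv",
    "generate_fixture",
    "load_run_config",
    "provenance_record",
    "FIXTURE_NAMES",
]

SIDECAR_KEYS = ("offsets_dmd_px", "offsets_nm", "mode", "config", "meta", "n_frames")

FIXTURE_NAMES = ("bead_cube", "filaments", "point_grid", "two_layer")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: RawStack, path) -> Path:
    """Write frames as multi-page 32-bit TIFF with a JSON metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    data = frames.astype(np.float32) if frames.dtype.kind == "f" else frames
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "n_frames": int(len(stack)),
        "offsets_dmd_px": [list(map(int, o)) for o in stack.offsets_dmd_px],
        "offsets_nm": [list(map(float, o)) for o in stack.offsets_nm],
        "mode": stack.mode,
        "config": stack.config.to_dict(),
        "meta": _jsonable(stack.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path, assume_defaults: bool = False) -> RawStack:
    """Read a TIFF + JSON sidecar pair back into a RawStack.

    Round-trips are lossless for float32 and integer data.  Without a
    sidecar, ``assume_defaults`` synthesizes the default 6x6 scan schedule
    (with a warning recorded in the stack metadata); otherwise the missing
    sidecar is an error listing the required keys.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = _sidecar_path(path)
    if not side.exists():
        if not assume_defaults:
            raise InvalidParameterError(
                f"missing sidecar {side.name}; required keys: {', '.join(SIDECAR_KEYS)}"
            )
        config = OpticalConfig()
        seq = multifocal_sequence(dmd_shape=(64, 64))
        if len(frames) != len(seq):
            raise InvalidParameterError(
                f"--assume-defaults expects {len(seq)} frames, got {len(frames)}"
            )
        warnings.warn("no sidecar: offsets synthesized from the default 6x6 schedule")
        d = config.dmd_pixel_sample
        return RawStack(
            frames=np.asarray(frames, dtype=np.float64),
            offsets_dmd_px=list(seq.offsets),
            offsets_nm=[(ox * d, oy * d) for ox, oy in seq.offsets],
            mode="wf",
            config=config,
            meta={
                "aperture": seq.aperture,
                "period": seq.period,
                "step": seq.step,
                "warnings": ["offsets synthesized from defaults"],
            },
        )
    sidecar = json.loads(side.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise InvalidParameterError(f"sidecar missing keys: {', '.join(missing)}")
    if sidecar["n_frames"] != len(frames) or len(sidecar["offsets_nm"]) != len(frames):
        raise InvalidParameterError(
            f"sidecar lists {len(sidecar['offsets_nm'])} offsets for "
            f"{len(frames)} frames"
        )
    return RawStack(
        frames=np.asarray(frames, dtype=np.float64),
        offsets_dmd_px=[tuple(o) for o in sidecar["offsets_dmd_px"]],
        offsets_nm=[tuple(o) for o in sidecar["offsets_nm"]],
        mode=sidecar["mode"],
        config=OpticalConfig.from_dict(sidecar["config"]),
        meta=sidecar["meta"],
    )


def write_psf(psf, path) -> Path:
    """Export a PSF as 32-bit TIFF with the voxel size in the description."""
    path = Path(path)
    tifffile.imwrite(
        path,
        psf.values.astype(np.float32),
        photometric="minisblack",
        description=json.dumps({"voxel_nm": list(psf.voxel), "kind": psf.kind}),
    )
    return path


def write_layout_csv(layout, path) -> Path:
    """Disk layout as CSV: x_um, y_um, r_um, theta_rad, sub_spiral."""
    path = Path(path)
    rec = layout.to_records()
    header = "x_um,y_um,r_um,theta_rad,sub_spiral"
    np.savetxt(path, rec, delimiter=",", header=header, comments="", fmt="%.6f")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def provenance_record(config_like: dict, inputs: dict[str, Path] | None = None, **extra) -> dict:
    """Provenance dict: config hash, input file hashes, free-form extras."""
    blob = json.dumps(_jsonable(config_like), sort_keys=True).encode()
    rec = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "input_sha256": {},
    }
    for name, p in (inputs or {}).items():
        rec["input_sha256"][name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    rec.update(_jsonable(extra))
    return rec


# --- run configuration -------------------------------------------------

_SCHEMA = {
    "optics": set(OpticalConfig().to_dict()),
    "pattern": {"aperture", "period", "step", "dmd_shape", "kind", "shift", "n_orientations"},
    "disk": {"n_sub_spirals", "pitch", "pinhole_diameter", "r_min", "r_max"},
    "simulate": {
        "phantom",
        "shape",
        "n_beads",
        "bead_diameter",
        "min_separation",
        "mode",
        "noise",
        "focal_plane_index",
    },
    "reconstruct": {
        "interpolation",
        "upsample_factor",
        "weighting",
        "deconvolve_iterations",
    },
    "seeds": None,  # free-form mapping stage -> int
}


def load_run_config(path) -> dict:
    """Load and validate a YAML run configuration (strict schema)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in cfg:
            continue
        extra = set(cfg[section]) - allowed
        if extra:
            raise InvalidParameterError(
                f"unknown keys in [{section}]: {sorted(extra)}"
            )
    for stage, s in (cfg.get("seeds") or {}).items():
        if not isinstance(s, int):
            raise InvalidParameterError(f"seed for stage {stage!r} must be an integer")
    return cfg


# --- fixtures ----------------------------------------------------------


def _fixture_phantom(name: str, shape, seed: int) -> Phantom3D:
    if name == "bead_cube":
        return bead_phantom(
            shape, n_beads=12, bead_diameter=200.0, min_separation=1200.0, seed=seed
        )
    if name == "filaments":
        return filament_phantom(shape, n_filaments=6, thickness=300.0, seed=seed)
    if name == "point_grid":
        return point_grid_phantom(shape, spacing_nm=2000.0)
    if name == "two_layer":
        return two_layer_phantom(shape)
    raise InvalidParameterError(
        f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}"
    )


def generate_fixture(
    name: str,
    out_dir,
    seed: int = 0,
    shape: tuple[int, int, int] = (33, 256, 256),
    config: OpticalConfig | None = None,
) -> dict[str, Path]:
    """Write a phantom, raw stacks in wf and sd modes, and ground truth JSON.

    Deterministic per seed: regenerating with the same seed reproduces every
    file bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or OpticalConfig(wavelength_ex=500.0, wavelength_em=500.0)
    phantom = _fixture_phantom(name, shape, seed)
    seq = multifocal_sequence(
        dmd_shape=_mask_shape_for(cfg, shape[1:])
    )
    files: dict[str, Path] = {}
    ph_path = out / f"{name}_phantom.tif"
    tifffile.imwrite(ph_path, phantom.values.astype(np.float32))
    files["phantom"] = ph_path
    for mode in ("wf", "sd_effective"):
        stack = simulate_stack(phantom, seq, cfg, mode=mode, seed=seed)
        p = out / f"{name}_{mode}.tif"
        write_stack(stack, p)
        files[mode] = p
    truth = {"kind": phantom.kind, "seed": seed, "shape": list(shape)}
    truth.update(_jsonable(phantom.meta))
    tp = out / f"{name}_truth.json"
    tp.write_text(json.dumps(truth, indent=1))
    files["truth"] = tp
    return files


def _mask_shape_for(config: OpticalConfig, sample_shape: tuple[int, int]) -> tuple[int, int]:
    """Smallest DMD mask grid covering a sample grid, rounded up to the period."""
    ny, nx = sample_shape
    f = config.camera_pixel_sample / config.dmd_pixel_sample
    return (int(np.ceil(ny * f)) + 16, int(np.ceil(nx * f)) + 16)
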