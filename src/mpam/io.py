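"""Format plumbing: TIFF/CSV/JSON readers and writers plus provenance sidecars.

Image stacks travel as multi-page TIFF (one page per depth slice or repeat),
tables as CSV with named columns, and every written artifact gets a JSON
sidecar recording the config hash, seed, software version and input files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .synthetic import ChannelPair, PAMScan, PKProfile


def write_tiff(path: str | Path, array: np.ndarray, dtype=np.float32) -> Path:
    """Write an array as TIFF; 3-D arrays become multi-page (first axis pages)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(array).astype(dtype)
    # grayscale pages, never RGB interpretation of a leading size-3/4 axis
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_sidecar(artifact: str | Path, config: RunConfig, inputs: list[str] | None = None) -> Path:
    """Provenance record next to an artifact: config, hash, seed, version, inputs."""
    artifact = Path(artifact)
    sidecar = artifact.with_suffix(artifact.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "artifact": artifact.name,
                "config_hash": config.hash(),
                "seed": config.seed,
                "version": __version__,
                "inputs": sorted(str(i) for i in (inputs or [])),
                "config": config.model_dump(),
            },
            indent=2,
            default=str,
        )
    )
    return sidecar


def save_pam_scan(scan: PAMScan, out_dir: str | Path, config: RunConfig) -> dict[str, Path]:
    """PAMScan to disk: per-wavelength volumes (pages = depth) + flow stacks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for wl in scan.wavelengths:
        # store depth-first pages for multi-page TIFF
        vol = np.moveaxis(scan.amp[wl], -1, 0)
        paths[f"amp{wl}"] = write_tiff(out / f"scan_{wl}nm.tif", vol)
    if scan.flow_stacks:
        stacks = np.stack([scan.flow_stacks[k] for k in sorted(scan.flow_stacks)])
        paths["flow"] = write_tiff(out / "flow_stacks.tif", stacks)
        (out / "flow_stacks.ids.json").write_text(json.dumps(sorted(scan.flow_stacks)))
    meta = {
        "wavelengths": list(scan.wavelengths),
        "prf_hz": scan.prf_hz,
        "pixel_size_um": scan.pixel_size_um,
        "beam_waist_um": scan.beam_waist_um,
    }
    (out / "scan_meta.json").write_text(json.dumps(meta, indent=2))
    for p in paths.values():
        write_sidecar(p, config)
    return paths


def load_pam_scan(in_dir: str | Path) -> PAMScan:
    """Read a PAMScan bundle written by :func:`save_pam_scan`."""
    src = Path(in_dir)
    meta = json.loads((src / "scan_meta.json").read_text())
    amp = {
        wl: np.moveaxis(read_tiff(src / f"scan_{wl}nm.tif"), 0, -1).astype(float)
        for wl in meta["wavelengths"]
    }
    flow_stacks = {}
    stack_path = src / "flow_stacks.tif"
    if stack_path.exists():
        ids = json.loads((src / "flow_stacks.ids.json").read_text())
        stacks = read_tiff(stack_path).astype(float)
        flow_stacks = {int(i): stacks[n] for n, i in enumerate(ids)}
    return PAMScan(
        amp=amp,
        flow_stacks=flow_stacks,
        wavelengths=tuple(meta["wavelengths"]),
        prf_hz=meta["prf_hz"],
        pixel_size_um=meta["pixel_size_um"],
        beam_waist_um=meta["beam_waist_um"],
    )


def save_channel_pair(pair: ChannelPair, out_dir: str | Path, config: RunConfig) -> Path:
    """Blue/red channels and backgrounds as a 4-page TIFF (documented order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pages = np.stack([pair.blue, pair.red, pair.blue_bg, pair.red_bg])
    path = write_tiff(out / "channels.tif", pages)
    (out / "channels.meta.json").write_text(
        json.dumps({"pages": ["blue", "red", "blue_bg", "red_bg"], "gain": pair.gain})
    )
    write_sidecar(path, config)
    return path


def load_channel_pair(in_dir: str | Path) -> ChannelPair:
    src = Path(in_dir)
    pages = read_tiff(src / "channels.tif").astype(float)
    meta = json.loads((src / "channels.meta.json").read_text())
    order = {name: i for i, name in enumerate(meta["pages"])}
    return ChannelPair(
        blue=pages[order["blue"]],
        red=pages[order["red"]],
        blue_bg=pages[order["blue_bg"]],
        red_bg=pages[order["red_bg"]],
        gain=meta.get("gain", 1.0),
    )


def save_table(df: pd.DataFrame, path: str | Path, config: RunConfig, inputs=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    write_sidecar(path, config, inputs)
    return path


def save_json(obj, path: str | Path, config: RunConfig, inputs=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify))
    write_sidecar(path, config, inputs)
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def save_pk_profile(profile: PKProfile, path: str | Path, config: RunConfig) -> Path:
    df = pd.DataFrame({"time_h": profile.time_h, "conc_pg_mg": profile.conc})
    return save_table(df, path, config)


def load_pk_profile(path: str | Path) -> PKProfile:
    df = pd.read_csv(path)
    return PKProfile(time_h=df["time_h"].to_numpy(), conc=df["conc_pg_mg"].to_numpy())
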