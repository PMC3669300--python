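"""Reading images/configs and writing result tables.

Images are single-channel grayscale TIFFs (8/12/16-bit or float); scan
metadata, ROIs and spike positions come from a YAML (or JSON) config file
whose paths are resolved relative to the config's own location.  Result
tables go to CSV and, optionally, XLSX.  Every table written embeds the
config hash, the seed and the software version so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .extract import ROI, LineScanImage
from .scantime import ScanConfig, ScanMode

__all__ = [
    "load_config",
    "config_hash",
    "scan_config_from_dict",
    "roi_from_value",
    "read_image",
    "write_image",
    "write_results",
    "write_trace_csv",
]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config; stores its directory under ``_dir``."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a mapping")
    cfg["_dir"] = str(path.parent.resolve())
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def scan_config_from_dict(block: dict[str, Any]) -> ScanConfig:
    """Build a ScanConfig from a config-file metadata block.

    Either a ``scan_speed_preset`` or the explicit keys ``mode``,
    ``line_frequency_hz``, ``pixels_per_line``, ``lines`` and
    ``pixel_integration_time_us`` are accepted.
    """
    if "scan_speed_preset" in block:
        return ScanConfig.from_preset(
            int(block["scan_speed_preset"]),
            mode=block.get("mode", "unidirectional"),
            n=int(block.get("pixels_per_line", 512)),
            m=int(block.get("lines", 512)),
            reconciled=bool(block.get("reconciled_tp", False)),
        )
    return ScanConfig(
        mode=ScanMode(block["mode"]),
        f=float(block["line_frequency_hz"]),
        n=int(block["pixels_per_line"]),
        m=int(block["lines"]),
        tp=float(block["pixel_integration_time_us"]),
    )


def roi_from_value(value: Any) -> ROI:
    """Accept ``[row_start, row_stop, col_start, col_stop]`` or a mapping."""
    if isinstance(value, dict):
        return ROI(**value)
    r0, r1, c0, c1 = (int(v) for v in value)
    return ROI(r0, r1, c0, c1)


def read_image(path: str | Path, config: ScanConfig, stimulus_onset: float = 0.0) -> LineScanImage:
    pixels = tifffile.imread(str(path))
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D x-t image, got shape {pixels.shape}")
    return LineScanImage(pixels=np.asarray(pixels, float), config=config,
                         stimulus_onset=stimulus_onset)


def write_image(path: str | Path, image: LineScanImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def _metadata(seed: Optional[int], cfg_hash: Optional[str]) -> dict[str, Any]:
    return {"spikefit_version": __version__, "seed": seed, "config_hash": cfg_hash}


def write_results(
    table: pd.DataFrame,
    out: str | Path,
    xlsx: bool = False,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> Path:
    """Write a results table to CSV (and XLSX alongside when requested).

    Provenance (version, seed, config hash) is embedded as ``# key=value``
    comment lines ahead of the CSV header.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    meta = _metadata(seed, cfg_hash)
    with open(out, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, index=False)
    if xlsx:
        xlsx_path = out.with_suffix(".xlsx")
        with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
            table.to_excel(writer, index=False, sheet_name="results")
            pd.DataFrame([meta]).to_excel(writer, index=False, sheet_name="provenance")
    return out


def write_trace_csv(trace, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": trace.times, "dF_F0": trace.values}).to_csv(out, index=False)
    return out
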