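"""File round-trips: TIFF stacks with metadata sidecars, SWC traces, CSV tables.

Stacks are written as single-channel multi-page TIFF (one page per z-plane,
16-bit unsigned) with a YAML sidecar carrying the voxel pitch and session
label; SWC files follow the standard 7-column text layout with coordinates
and radii in µm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import ImageStack

__all__ = [
    "FormatError",
    "load_stack",
    "save_stack",
    "load_swc",
    "save_swc",
    "sidecar_path",
]

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".yaml")


def save_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a YAML metadata sidecar.

    Intensities are rounded and clipped to the uint16 range; stacks produced
    by the renderer with noise enabled already hold integer photon counts,
    so the round trip is lossless for them.
    """
    path = Path(path)
    data = np.clip(np.rint(stack.intensities), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    meta = {
        "voxel_pitch_um": [float(p) for p in stack.voxel_pitch_um],
        "session": stack.session,
        "axes": "ZYX",
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def load_stack(path) -> ImageStack:
    """Read a TIFF stack; the YAML sidecar with the voxel pitch is required."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(
            f"missing metadata sidecar {side.name}: voxel pitch unknown"
        )
    try:
        meta = yaml.safe_load(side.read_text())
        pitch = tuple(float(p) for p in meta["voxel_pitch_um"])
        session = str(meta.get("session", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed sidecar {side.name}: {exc}") from exc
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types
        raise FormatError(f"cannot read TIFF {path.name}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    return ImageStack(data.astype(np.float64), pitch, session)


def save_swc(path, points_um: np.ndarray, radii_um: np.ndarray,
             parents=None, node_type: int = 3) -> Path:
    """Write an SWC trace. Default parents chain each node to the previous one."""
    points_um = np.asarray(points_um, dtype=np.float64)
    radii_um = np.asarray(radii_um, dtype=np.float64)
    n = len(points_um)
    if parents is None:
        parents = [-1] + list(range(1, n))  # 1-based parent ids
    lines = ["# id type x y z radius parent"]
    for i in range(n):
        x, y, z = points_um[i]
        lines.append(
            f"{i + 1} {node_type} {x:.6f} {y:.6f} {z:.6f} {radii_um[i]:.6f} "
            f"{parents[i]}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def load_swc(path) -> pd.DataFrame:
    """Read an SWC file into a DataFrame with columns id..parent (µm units)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise FormatError(f"malformed SWC line: {line!r}")
        rows.append(
            (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
             float(parts[4]), float(parts[5]), int(parts[6]))
        )
    return pd.DataFrame(rows, columns=SWC_COLUMNS)
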