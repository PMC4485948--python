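"""Reading and writing stacks, paths and reports.

Stacks live in a directory of index-named TIFF/PNG slice images plus a
YAML metadata sidecar (``pixel_size_um``, ``slice_thickness_um``).
Tracked paths are exported as CSV (x, y, z, radius, source) and SWC (the
standard neuron-morphology tracing format; the type field distinguishes
automatic from manually corrected points).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import SliceStack
from .tracker import PathPoint, TrackedPath

__all__ = [
    "read_stack",
    "write_stack",
    "write_path_csv",
    "read_path_csv",
    "write_path_swc",
    "write_report",
]

METADATA_NAMES = ("metadata.yaml", "metadata.yml", "metadata.json")
_INDEX_RE = re.compile(r"(\d+)\D*$")

SWC_TYPE_AUTO = 2
SWC_TYPE_MANUAL = 3


def _slice_index(path: Path) -> int | None:
    m = _INDEX_RE.search(path.stem)
    return int(m.group(1)) if m else None


def read_stack(directory) -> SliceStack:
    """Load an index-ordered TIFF/PNG slice directory into a stack.

    Slice order follows the numeric index embedded in each filename; the
    index range must be contiguous.  All slices must share one size.
    Integer images are rescaled to [0, 1].
    """
    directory = Path(directory)
    files: dict[int, Path] = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        idx = _slice_index(p)
        if idx is None:
            raise ValueError(f"cannot parse a slice index from file name {p.name!r}")
        if idx in files:
            raise ValueError(f"duplicate slice index {idx} ({p.name} vs {files[idx].name})")
        files[idx] = p
    if not files:
        raise FileNotFoundError(f"no TIFF/PNG slices found in {directory}")
    lo, hi = min(files), max(files)
    missing = [i for i in range(lo, hi + 1) if i not in files]
    if missing:
        raise ValueError(f"missing slice indices: {missing}")

    slices = []
    shape = None
    for i in range(lo, hi + 1):
        try:
            img = iio.imread(files[i])
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise OSError(f"cannot read slice file {files[i].name}: {exc}") from exc
        if np.issubdtype(img.dtype, np.integer):
            img = img.astype(float) / np.iinfo(img.dtype).max
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"slice {files[i].name} has shape {img.shape}, expected {shape}"
            )
        slices.append(img)

    meta = {}
    for name in METADATA_NAMES:
        mp = directory / name
        if mp.exists():
            text = mp.read_text()
            meta = json.loads(text) if name.endswith(".json") else yaml.safe_load(text)
            break
    return SliceStack(
        np.stack(slices),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        slice_thickness=float(meta.get("slice_thickness_um", 2.5)),
    )


def write_stack(stack: SliceStack, directory, binary: bool = False) -> None:
    """Write a stack as numbered TIFF slices plus a metadata sidecar.

    With ``binary=True`` slices are saved as 0/255 uint8 masks (the
    round-trippable form for preprocessed stacks).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(stack.n_slices - 1)))
    for i in range(stack.n_slices):
        img = np.asarray(stack.slices[i])
        if binary:
            img = (img > 0).astype(np.uint8) * 255
        else:
            img = np.clip(img, 0, 1)
            img = (img * 65535).round().astype(np.uint16)
        tifffile.imwrite(directory / f"{i:0{width}d}.tif", img)
    (directory / "metadata.yaml").write_text(
        yaml.safe_dump(
            {
                "pixel_size_um": float(stack.pixel_size),
                "slice_thickness_um": float(stack.slice_thickness),
                "n_slices": int(stack.n_slices),
            }
        )
    )


def write_path_csv(path: TrackedPath, file) -> None:
    df = pd.DataFrame(
        [{"x": p.x, "y": p.y, "z": p.z, "radius": p.radius, "source": p.source} for p in path.points]
    )
    df.to_csv(file, index=False)


def read_path_csv(file) -> TrackedPath:
    df = pd.read_csv(file)
    return TrackedPath(
        [
            PathPoint(float(r.x), float(r.y), int(r.z), float(r.radius), str(r.source))
            for r in df.itertuples()
        ]
    )


def write_path_swc(path: TrackedPath, file, slice_thickness_px: float = 1.0) -> None:
    """SWC export: ``id type x y z radius parent``, chained in path order.

    The type column is 2 for automatically tracked points and 3 for
    manually supplied bridge points; z is scaled by the slice thickness
    in pixel units so the geometry is isotropic.
    """
    lines = ["# id type x y z radius parent"]
    for i, p in enumerate(path.points):
        t = SWC_TYPE_MANUAL if p.source == "manual" else SWC_TYPE_AUTO
        parent = -1 if i == 0 else i
        lines.append(
            f"{i + 1} {t} {p.x:.2f} {p.y:.2f} {p.z * slice_thickness_px:.2f} "
            f"{p.radius:.2f} {parent}"
        )
    Path(file).write_text("\n".join(lines) + "\n")


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


def write_report(report: dict, file) -> None:
    Path(file).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
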