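"""Image and result I/O.

Reads 8/16-bit grayscale TIFF or PNG into :class:`~rotmorph.image.GrayImage`
(RGB inputs are converted by luminance with a warning), and writes the
pipeline outputs: mask, red-overlay visualization, per-spot CSV,
intensity-histogram CSV and a JSON run manifest. All exported coordinates
are 0-based (row, col).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import GrayImage
from .pipeline import PipelineResult

__all__ = ["read_image", "write_image", "make_overlay", "write_outputs"]

logger = logging.getLogger("rotmorph")

SPOT_CSV_COLUMNS = [
    "id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "feret_px",
    "feret_physical",
    "intensity_sum",
]


def read_image(path) -> GrayImage:
    """Read a grayscale TIFF/PNG; 16-bit data keeps its native range."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            logger.warning("%s is multichannel; converting to luminance", path)
            arr = (
                0.2126 * arr[..., 0] + 0.7152 * arr[..., 1] + 0.0722 * arr[..., 2]
            ).astype(arr.dtype)
        else:
            raise ValueError(f"{path}: ambiguous multichannel layout {arr.shape}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got {arr.shape}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr, bit_depth=bit_depth)


def write_image(path, array: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, array)
    else:
        iio.imwrite(path, array)


def make_overlay(image: np.ndarray, mask: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """RGB copy of *image* with masked pixels alpha-blended toward red.

    With an empty mask this is pixel-identical to a gray-to-RGB copy.
    """
    gray = np.asarray(image)
    if gray.dtype != np.uint8:
        lo, hi = float(gray.min()), float(gray.max())
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        gray = ((gray - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1).astype(np.float64)
    on = np.asarray(mask) > 0
    rgb[on, 0] = (1 - alpha) * rgb[on, 0] + alpha * 255.0
    rgb[on, 1] *= 1 - alpha
    rgb[on, 2] *= 1 - alpha
    return np.rint(rgb).astype(np.uint8)


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_outputs(
    out_dir,
    result: PipelineResult,
    image: GrayImage,
    config,
    resolution: float = 1.0,
    unit: str = "px",
    seed: int | None = None,
    stem: str = "spots",
) -> dict[str, Path]:
    """Write mask TIFF, overlay PNG, spots CSV, histogram CSV and the run
    manifest; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": out_dir / f"{stem}_mask.tif",
        "overlay": out_dir / f"{stem}_overlay.png",
        "spots": out_dir / f"{stem}.csv",
        "histogram": out_dir / f"{stem}_histogram.csv",
        "manifest": out_dir / f"{stem}_manifest.json",
    }
    write_image(paths["mask"], result.mask)
    write_image(paths["overlay"], make_overlay(image.pixels, result.mask))
    pd.DataFrame(
        [
            {
                "id": r.label,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area,
                "feret_px": r.feret_px,
                "feret_physical": r.feret_physical,
                "intensity_sum": r.intensity_sum,
            }
            for r in result.records
        ],
        columns=SPOT_CSV_COLUMNS,
    ).to_csv(paths["spots"], index=False)
    counts, edges = result.histogram
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(paths["histogram"], index=False)

    import numpy as _np
    import scipy as _scipy
    import skimage as _skimage

    manifest = {
        "config": _jsonable(config),
        "resolution": resolution,
        "unit": unit,
        "seed": seed,
        "n_spots": len(result.records),
        "coordinate_convention": "0-based (row, col)",
        "versions": {
            "python": platform.python_version(),
            "numpy": _np.__version__,
            "scipy": _scipy.__version__,
            "scikit-image": _skimage.__version__,
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    for name, p in paths.items():
        logger.info("wrote %s: %s", name, p)
    return paths
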