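"""Reading and writing the pipeline's on-disk artifacts.

Images travel as grayscale TIFF (single-page for 2D, multi-page for
z-stacks) with physical pixel/voxel sizes supplied alongside; synthetic
ground truth and results are JSON sidecars sharing the image basename;
angular profiles and tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import AngularProfile, Image2D, ImageStack3D, asdict

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "write_sidecar",
    "read_sidecar",
    "write_profile_csv",
    "read_profile_csv",
    "write_result_json",
]


def read_image(path, pixel_size_um: float = 1.0) -> Image2D:
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Image2D(np.asarray(data, dtype=float), pixel_size_um)


def write_image(path, image: Image2D) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def read_stack(path, voxel_size_um=(1.0, 1.0, 1.0)) -> ImageStack3D:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack3D(np.asarray(data, dtype=float), tuple(voxel_size_um))


def write_stack(path, stack: ImageStack3D) -> None:
    tifffile.imwrite(path, stack.voxels.astype(np.float32))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(image_path, payload: dict) -> Path:
    """Ground-truth/parameter sidecar next to an image, same basename."""
    p = Path(image_path).with_suffix(".json")
    p.write_text(json.dumps(_jsonable(payload), indent=2))
    return p


def read_sidecar(image_path) -> dict:
    return json.loads(Path(image_path).with_suffix(".json").read_text())


def write_profile_csv(path, profile: AngularProfile) -> None:
    pd.DataFrame(
        {"angle_deg": profile.angles_deg, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def read_profile_csv(path, normalized: bool = False) -> AngularProfile:
    df = pd.read_csv(path)
    return AngularProfile(
        df["angle_deg"].to_numpy(), df["intensity"].to_numpy(), normalized
    )


def write_result_json(path, result) -> None:
    """Serialize any result dataclass (AlignmentResult, ContractionResult, ...)."""
    payload = result if isinstance(result, dict) else asdict(result)
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))
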