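"""TIFF stack and sidecar-metadata I/O, plus run configuration.

Stacks are stored as multi-page grayscale TIFF (8- or 16-bit) with a YAML
sidecar (``<stem>.yaml`` next to the TIFF) carrying acquisition metadata —
frame rate, exposure time, pixel pitch, seed — and, for synthetic stacks,
the generator ground truth.  Values given explicitly to ``read_stack``
override the sidecar, which overrides nothing (there are no silent
defaults for the frame rate: a stack without one is an error).

Pixel coordinates are 0-based, half-open, (row, col) order throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .errors import FormatError
from .metrics import DEFAULT_PIXEL_PITCH_UM, SpeckleFrame, SpeckleStack
from .synthetic import GroundTruth

__all__ = ["RunConfig", "read_stack", "write_stack", "sidecar_path", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run.

    ``roi`` is ``(row0, col0, height, width)`` in 0-based half-open pixel
    coordinates; ``None`` means the full frame.
    """

    input_path: Path
    output_dir: Path
    roi: Optional[tuple[int, int, int, int]] = None
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_rate_hz: Optional[float] = None
    exposure_time_s: Optional[float] = None
    group_label: str = ""
    flow_axis: Optional[int] = None  # None: skip the flow-speed stage
    roi_length_mm: float = 0.8
    seed: int = 0

    def validate(self, image_shape: Optional[tuple[int, int]] = None) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(f"input path does not exist: {self.input_path}")
        if self.roi is not None:
            r0, c0, h, w = self.roi
            if min(r0, c0, h, w) < 0 or h == 0 or w == 0:
                raise ValueError(f"invalid ROI {self.roi}")
            if image_shape is not None:
                rows, cols = image_shape
                if r0 + h > rows or c0 + w > cols:
                    raise ValueError(
                        f"ROI {self.roi} exceeds image bounds {image_shape}"
                    )


def sidecar_path(tiff_path: Path | str) -> Path:
    return Path(tiff_path).with_suffix(".yaml")


def config_hash(params: dict) -> str:
    """Stable short hash of a resolved parameter dictionary."""
    blob = yaml.safe_dump(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_stack(
    path: Path | str,
    stack: SpeckleStack,
    seed: Optional[int] = None,
    ground_truth: Optional[GroundTruth] = None,
) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a YAML sidecar.

    Intensities are rounded and saturation-clipped to the uint16 range,
    matching sCMOS output convention.  Returns the sidecar path.
    """
    path = Path(path)
    data = stack.as_array()
    data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")

    meta: dict = {
        "frame_rate_hz": float(stack.frame_rate_hz),
        "exposure_time_s": float(stack.exposure_time_s),
        "pixel_pitch_um": float(stack.frames[0].pixel_pitch_um),
        "n_frames": len(stack),
    }
    if seed is not None:
        meta["seed"] = int(seed)
    if ground_truth is not None:
        gt = {k: v for k, v in dataclasses.asdict(ground_truth).items()
              if v is not None and not isinstance(v, np.ndarray)}
        meta["ground_truth"] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in gt.items()
        }
    side = sidecar_path(path)
    side.write_text(yaml.safe_dump(meta, sort_keys=True))
    return side


def read_stack(
    path: Path | str,
    frame_rate_hz: Optional[float] = None,
    exposure_time_s: Optional[float] = None,
    pixel_pitch_um: Optional[float] = None,
) -> SpeckleStack:
    """Read a multi-page grayscale TIFF as a SpeckleStack.

    Metadata resolution order: explicit arguments, then the YAML sidecar.
    A missing frame rate after both sources is an error naming the field.

    Raises
    ------
    FormatError
        For RGB pages (grayscale required) or mixed page shapes.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if any(len(s) != 2 for s in shapes):
            raise FormatError(
                f"{path}: RGB/multichannel pages not supported; "
                f"convert to grayscale"
            )
        if len(shapes) != 1:
            raise FormatError(f"{path}: mixed page shapes {sorted(shapes)}")
        data = np.stack([p.asarray() for p in tf.pages])

    meta: dict = {}
    side = sidecar_path(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}

    frame_rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if frame_rate is None:
        raise FormatError(
            f"{path}: frame_rate_hz missing — provide it explicitly or in the "
            f"sidecar {side.name}"
        )
    exposure = exposure_time_s if exposure_time_s is not None else meta.get(
        "exposure_time_s", 1.0 / frame_rate)
    pitch = pixel_pitch_um if pixel_pitch_um is not None else meta.get(
        "pixel_pitch_um", DEFAULT_PIXEL_PITCH_UM)

    frames = tuple(
        SpeckleFrame(
            intensity=page.astype(float),
            pixel_pitch_um=float(pitch),
            timestamp_s=i / float(frame_rate),
        )
        for i, page in enumerate(data)
    )
    return SpeckleStack(
        frames=frames,
        frame_rate_hz=float(frame_rate),
        exposure_time_s=float(exposure),
    )
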