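"""Speckle-pattern metrics: normalized autocovariance, speckle size, contrast.

The two observables this package is built around are

* the **speckle size** ``s`` — the width of the central peak of the
  normalized spatial autocovariance of an intensity image, and
* the **speckle contrast** ``C = sigma / <I>`` — the ratio of the intensity
  standard deviation to the mean over a region.

For polarized, fully developed speckle the static contrast is 1; scatterer
motion within the exposure blurs the pattern and drives the contrast toward
0, while aggregation of scatterers (e.g. activated platelets) enlarges the
speckle grains.

Conventions
-----------
* The autocovariance is the *linear* (zero-padded, overlap-normalized)
  covariance of the mean-subtracted image, normalized so the zero-lag value
  is exactly 1.  Circular wrap-around would bias widths for large grains.
* The scalar speckle size is the full width at half maximum (FWHM) of the
  central peak, measured along each lag axis with linear sub-pixel
  interpolation and averaged over the two axes.
* Contrast uses the sample (n-1) standard deviation.
* Pixel coordinates are 0-based, half-open, (row, col) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "SpeckleFrame",
    "SpeckleStack",
    "AutocovarianceMap",
    "SpeckleSizeResult",
    "ContrastResult",
    "MetricTimeSeries",
    "compute_autocovariance",
    "estimate_speckle_size",
    "compute_contrast",
    "compute_timeseries",
    "DEFAULT_PIXEL_PITCH_UM",
]

#: Default object-plane pixel pitch in micrometres: 6.5 um sCMOS pixel
#: behind a 4x objective.  This is a documented assumption — the reference
#: measurements do not state whether sizes are image- or object-plane.
DEFAULT_PIXEL_PITCH_UM = 6.5 / 4.0


@dataclass(frozen=True)
class SpeckleFrame:
    """A single 2D intensity image with acquisition metadata.

    Attributes
    ----------
    intensity:
        2D array of nonnegative, finite intensities (arbitrary units).
    pixel_pitch_um:
        Physical size of one pixel at the reference plane, in micrometres.
    timestamp_s:
        Acquisition time of the frame, in seconds.
    """

    intensity: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"intensity must be 2D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity must be finite")
        if np.any(arr < 0):
            raise ValueError("intensity must be nonnegative")
        object.__setattr__(self, "intensity", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class SpeckleStack:
    """An ordered time series of same-shaped speckle frames."""

    frames: tuple[SpeckleFrame, ...]
    frame_rate_hz: float
    exposure_time_s: float

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("stack must contain at least one frame")
        shape = frames[0].shape
        if any(f.shape != shape for f in frames):
            raise ValueError("all frames in a stack must share one shape")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> SpeckleFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack intensities into a (n_frames, rows, cols) float array."""
        return np.stack([f.intensity for f in self.frames])


@dataclass(frozen=True)
class AutocovarianceMap:
    """Normalized 2D autocovariance over spatial lags.

    ``values[center_index]`` is the zero-lag point and equals 1 exactly;
    the map is symmetric under lag negation.
    """

    values: np.ndarray
    center_index: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SpeckleSizeResult:
    """Scalar speckle size with per-axis widths and unit conversion."""

    size_px: float
    size_um: float
    size_x_px: float
    size_y_px: float
    method: str = "fwhm"


@dataclass(frozen=True)
class ContrastResult:
    """Speckle contrast C = sd/mean with its ingredients."""

    contrast: float
    mean_intensity: float
    sd_intensity: float


@dataclass(frozen=True)
class MetricTimeSeries:
    """Per-frame size and contrast series; NaN marks frames that failed
    metric preconditions (they are flagged, never dropped)."""

    times_s: np.ndarray
    sizes_um: np.ndarray
    sizes_px: np.ndarray
    contrasts: np.ndarray
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.times_s)
        for name in ("sizes_um", "sizes_px", "contrasts"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")


def compute_autocovariance(frame: SpeckleFrame | np.ndarray) -> AutocovarianceMap:
    """Normalized linear autocovariance of an intensity image.

    The image mean is subtracted, the covariance is computed through the
    Wiener–Khinchin route (power spectrum of the zero-padded, mean-subtracted
    image, inverse transformed), each lag is divided by its overlap count to
    remove the triangular windowing bias, and the map is normalized by its
    zero-lag value so the center equals exactly 1.

    Zero-padding to at least twice each dimension makes the covariance
    linear (aperiodic) rather than circular.

    Raises
    ------
    DegenerateInputError
        If the image has zero variance (constant image).
    """
    img = frame.intensity if isinstance(frame, SpeckleFrame) else np.asarray(frame, float)
    n_rows, n_cols = img.shape
    centered = img - img.mean()
    if not np.any(centered):
        raise DegenerateInputError(
            "constant image: autocovariance normalization undefined"
        )

    # Linear correlation via zero-padding to >= 2x each dimension.
    pad_r, pad_c = 2 * n_rows, 2 * n_cols
    spec = np.fft.rfft2(centered, s=(pad_r, pad_c))
    raw = np.fft.irfft2(spec * np.conj(spec), s=(pad_r, pad_c))
    raw = np.fft.fftshift(raw)
    # Crop to the meaningful lag range [-(n-1), n-1] on each axis.
    cr, cc = pad_r // 2, pad_c // 2
    raw = raw[cr - (n_rows - 1): cr + n_rows, cc - (n_cols - 1): cc + n_cols]

    # Overlap counts are separable: (n - |dr|)(n - |dc|).
    lag_r = np.arange(-(n_rows - 1), n_rows)
    lag_c = np.arange(-(n_cols - 1), n_cols)
    counts = np.outer(n_rows - np.abs(lag_r), n_cols - np.abs(lag_c)).astype(float)
    cov = raw / counts

    center = (n_rows - 1, n_cols - 1)
    norm = cov[center]
    values = cov / norm
    values[center] = 1.0  # exact by construction
    return AutocovarianceMap(values=values, center_index=center)


def _fwhm_profile(profile: np.ndarray, center: int) -> float:
    """FWHM of the central peak of a 1D normalized profile.

    Walks outward from ``center`` to the first crossing below 0.5 on each
    side, with linear interpolation between the straddling samples.  A
    sample exactly at 0.5 counts as the crossing.  If secondary lobes rise
    above 0.5 beyond the first crossing, the first crossing is used and a
    warning is emitted.
    """
    half = 0.5

    def _cross(direction: int) -> float:
        prev = profile[center]
        i = center
        while True:
            i += direction
            if i < 0 or i >= len(profile):
                raise DegenerateInputError(
                    "autocovariance peak never falls below half maximum: "
                    "grain size is at least the field of view"
                )
            cur = profile[i]
            if cur <= half:
                if cur == half or prev == cur:
                    return abs(i - center)
                # linear interpolation between prev (>half) and cur (<half)
                frac = (prev - half) / (prev - cur)
                return abs(i - direction - center) + frac
            prev = cur

    left = _cross(-1)
    right = _cross(+1)

    # Secondary lobes above half maximum outside the central lobe?  The
    # scan is limited to lags with substantial sample overlap (|lag| <=
    # a quarter of the axis) — near the map edge the overlap-normalized
    # estimate is dominated by sampling noise and carries no lobe signal.
    max_lag = max(len(profile) // 4, int(np.ceil(max(left, right))) + 2)
    for direction, width in ((-1, left), (+1, right)):
        lo = int(np.ceil(width)) + 1
        idx = center + direction * np.arange(lo, max_lag + 1)
        idx = idx[(idx >= 0) & (idx < len(profile))]
        if idx.size and np.any(profile[idx] > half):
            warnings.warn(
                "secondary autocovariance lobe above half maximum; "
                "using first crossing",
                stacklevel=3,
            )
            break
    return left + right


def estimate_speckle_size(
    acov: AutocovarianceMap,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> SpeckleSizeResult:
    """Speckle size from a normalized autocovariance map.

    The full width at half maximum of the central peak is measured along
    each lag axis through the center with linear sub-pixel interpolation;
    the scalar size is the mean of the two axis widths ("average speckle
    size"), converted to micrometres by ``pixel_pitch_um``.
    """
    cy, cx = acov.center_index
    profile_y = acov.values[:, cx]  # width along the row (y) axis
    profile_x = acov.values[cy, :]  # width along the column (x) axis
    size_y = _fwhm_profile(profile_y, cy)
    size_x = _fwhm_profile(profile_x, cx)
    size_px = 0.5 * (size_x + size_y)
    return SpeckleSizeResult(
        size_px=size_px,
        size_um=size_px * pixel_pitch_um,
        size_x_px=size_x,
        size_y_px=size_y,
        method="fwhm",
    )


def compute_contrast(
    frame: SpeckleFrame | np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
) -> ContrastResult:
    """Speckle contrast C = sigma / <I> over the frame or a rectangular ROI.

    Uses the sample (n-1) standard deviation.  ``roi`` is
    ``(row0, col0, height, width)`` in 0-based half-open pixel coordinates.

    Raises
    ------
    DegenerateInputError
        If the (ROI) mean intensity is zero.
    """
    img = frame.intensity if isinstance(frame, SpeckleFrame) else np.asarray(frame, float)
    if roi is not None:
        r0, c0, h, w = roi
        img = img[r0:r0 + h, c0:c0 + w]
        if img.size == 0:
            raise ValueError("ROI selects no pixels")
    mean = float(img.mean())
    if mean <= 0:
        raise DegenerateInputError("zero-mean frame: contrast undefined")
    sd = float(img.std(ddof=1))
    return ContrastResult(contrast=sd / mean, mean_intensity=mean, sd_intensity=sd)


def compute_timeseries(
    stack: SpeckleStack,
    roi: tuple[int, int, int, int] | None = None,
) -> MetricTimeSeries:
    """Per-frame speckle size and contrast over a stack.

    Frames failing metric preconditions (constant or zero-mean images, peaks
    wider than the field of view) are recorded as NaN with a flag naming the
    failure; they are never silently dropped, so output length always equals
    the number of frames.
    """
    # Frame timestamps are used when they are strictly increasing;
    # otherwise times are derived from the frame rate.
    stamps = np.array([f.timestamp_s for f in stack.frames], float)
    if len(stamps) > 1 and not np.all(np.diff(stamps) > 0):
        stamps = np.arange(len(stamps)) / stack.frame_rate_hz

    sizes_px, sizes_um, contrasts, flags = [], [], [], []
    n_ok = 0
    for i, frame in enumerate(stack.frames):
        sub = frame
        if roi is not None:
            r0, c0, h, w = roi
            sub = SpeckleFrame(
                intensity=frame.intensity[r0:r0 + h, c0:c0 + w],
                pixel_pitch_um=frame.pixel_pitch_um,
                timestamp_s=frame.timestamp_s,
            )
        try:
            acov = compute_autocovariance(sub)
            size = estimate_speckle_size(acov, sub.pixel_pitch_um)
            contrast = compute_contrast(sub)
        except DegenerateInputError as exc:
            sizes_px.append(np.nan)
            sizes_um.append(np.nan)
            contrasts.append(np.nan)
            flags.append(f"frame {i}: {exc}")
            continue
        sizes_px.append(size.size_px)
        sizes_um.append(size.size_um)
        contrasts.append(contrast.contrast)
        flags.append("")
        n_ok += 1
    if n_ok == 0:
        raise DegenerateInputError("every frame in the stack is degenerate")
    return MetricTimeSeries(
        times_s=stamps,
        sizes_um=np.asarray(sizes_um),
        sizes_px=np.asarray(sizes_px),
        contrasts=np.asarray(contrasts),
        flags=tuple(flags),
    )
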