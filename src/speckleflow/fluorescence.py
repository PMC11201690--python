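"""Relative fluorescence intensity scoring of platelet aggregates.

DiOC6-labeled aggregates appear as bright regions on a darker background.
The aggregation score compares the mean signal intensity ``I_s`` inside a
selected signal region of ``A`` pixels with the mean background intensity
``I_b``:

* ``literal`` mode: ``1 - (A * I_b / I_s)`` — the published formula,
  implemented verbatim.  Note it is not scale-free in ``A`` (a large raw
  pixel count drives the score far below zero), so a
* ``normalized`` mode: ``1 - I_b / I_s`` — an area-free variant invariant
  under multiplicative intensity rescaling — is offered alongside.

Both modes equal 1 exactly when the background is perfectly dark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError
from .metrics import SpeckleFrame

__all__ = ["FluorescenceROI", "relative_fluorescence", "segment_signal"]

#: Pixels eroded off the background (complement) region to avoid blob-halo
#: contamination of the background estimate.
BACKGROUND_EROSION_PX = 3


@dataclass(frozen=True)
class FluorescenceROI:
    """Signal/background region statistics of a fluorescence image.

    ``A`` is the total pixel count of the signal region, ``I_s`` the mean
    intensity within it, and ``I_b`` the mean of the background region.
    The two regions never overlap.
    """

    A: int
    I_s: float
    I_b: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.I_s < 0 or self.I_b < 0:
            raise ValueError("intensities must be >= 0")


def relative_fluorescence(roi: FluorescenceROI, mode: str = "literal") -> float:
    """Relative fluorescence intensity score of a signal/background ROI.

    Parameters
    ----------
    mode:
        ``"literal"`` (default): ``1 - (A * I_b / I_s)``.
        ``"normalized"``: ``1 - I_b / I_s``.

    Raises
    ------
    DegenerateInputError
        If ``I_s`` is zero (score undefined).
    """
    if mode not in ("literal", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    if roi.I_s == 0:
        raise DegenerateInputError("I_s = 0: relative fluorescence undefined")
    if mode == "literal":
        return 1.0 - roi.A * roi.I_b / roi.I_s
    return 1.0 - roi.I_b / roi.I_s


def segment_signal(
    frame: SpeckleFrame | np.ndarray,
    threshold_method: str = "otsu",
) -> tuple[FluorescenceROI, np.ndarray]:
    """Automatic signal/background segmentation of a fluorescence image.

    The signal mask is a global Otsu threshold (``"otsu"``: above-threshold
    pixels; ``"otsu-inverted"``: below-threshold pixels, for
    inverted-contrast images).  The background region is the complement of
    the signal mask eroded by ``BACKGROUND_EROSION_PX`` pixels so blob
    halos do not contaminate the background mean.

    Returns the ROI statistics together with the boolean signal mask.
    An image yielding an empty signal mask produces a warning and
    ``A = 0`` (the literal score is then undefined).
    """
    img = frame.intensity if isinstance(frame, SpeckleFrame) else np.asarray(frame, float)
    if threshold_method not in ("otsu", "otsu-inverted"):
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    if np.ptp(img) == 0:
        mask = np.zeros(img.shape, bool)
    else:
        level = threshold_otsu(img)
        # For "otsu-inverted" the caller supplies an inverted-contrast image,
        # so below-threshold pixels are the bright objects of the original.
        mask = img > level if threshold_method == "otsu" else img < level

    if not mask.any():
        warnings.warn("empty signal mask: no fluorescence signal found",
                      stacklevel=2)
        background = binary_erosion(~mask, iterations=BACKGROUND_EROSION_PX)
        roi = FluorescenceROI(A=0, I_s=0.0, I_b=float(img[background].mean()))
        return roi, mask

    background = binary_erosion(~mask, iterations=BACKGROUND_EROSION_PX)
    if not background.any():
        background = ~mask
    roi = FluorescenceROI(
        A=int(mask.sum()),
        I_s=float(img[mask].mean()),
        I_b=float(img[background].mean()),
    )
    return roi, mask
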