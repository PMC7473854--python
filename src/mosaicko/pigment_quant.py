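"""Eye-pigmentation quantification from grayscale images.

Loss of retinal pigmentation is a convenient visual readout of biallelic
knockout of pigmentation genes (e.g. *tyrosinase*) in tadpoles: the darker
the eye, the more pigment-producing (non-knockout) cells remain.  The
score is computed in two steps on pre-cropped single-eye images:

1. :func:`mask_pigment` counts pixels whose 8-bit intensity falls in a
   dark band (default [1, 30], bounds inclusive) — the pigmented area.
2. :func:`normalize_pigment` maps that count to a [0, 1] phenotype score
   relative to the most pigmented reference eye of the batch:
   ``(max_ref - masked_pixels) / max_ref``, so 0 means fully pigmented
   (no knockout phenotype) and 1 means no detectable pigment.

``max_ref`` is an explicit parameter, never auto-detected, so scores are
reproducible across batches.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["mask_pigment", "normalize_pigment", "load_grayscale"]

#: Rec. 601 luminance weights used for RGB -> 8-bit grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def load_grayscale(path: str | Path, convert: bool = False) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit single-channel array.

    RGB(A) input is only accepted with ``convert=True``, in which case the
    standard luminance weights (0.299, 0.587, 0.114) are applied and the
    result rounded to uint8.
    """
    import imageio.v3 as iio

    img = iio.imread(path)
    return _as_gray8(img, convert=convert)


def _as_gray8(img: np.ndarray, convert: bool = False) -> np.ndarray:
    if img.ndim == 3:
        if not convert:
            raise ValueError(
                "multi-channel image; pass convert=True for luminance conversion"
            )
        img = np.round(img[..., :3].astype(float) @ _LUMA).astype(np.uint8)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit pixels, got dtype {img.dtype}; convert upstream"
        )
    return img


def mask_pigment(
    image: np.ndarray | str | Path,
    low: int = 1,
    high: int = 30,
    convert: bool = False,
) -> int:
    """Count pixels with intensity in [low, high] inclusive (the pigment mask).

    ``image`` may be an array or a path; arrays must be 8-bit grayscale
    unless ``convert=True`` allows luminance conversion of RGB input.
    Deterministic and invariant to pixel order.
    """
    if isinstance(image, (str, Path)):
        img = load_grayscale(image, convert=convert)
    else:
        img = _as_gray8(np.asarray(image), convert=convert)
    if not 0 <= low <= high <= 255:
        raise ValueError(f"invalid threshold band [{low}, {high}]")
    return int(np.count_nonzero((img >= low) & (img <= high)))


def normalize_pigment(masked_pixels: int, max_ref: int) -> float:
    """Phenotype score relative to the batch's most pigmented eye.

    ``(max_ref - masked_pixels) / max_ref``; a count exceeding the
    reference clips to 0 with a logged warning.
    """
    if max_ref <= 0:
        raise ValueError(f"max_ref must be positive, got {max_ref}")
    if masked_pixels < 0:
        raise ValueError("masked_pixels must be non-negative")
    score = (max_ref - masked_pixels) / max_ref
    if score < 0:
        logger.warning(
            "masked_pixels %d exceeds reference %d; clipping score to 0",
            masked_pixels,
            max_ref,
        )
        return 0.0
    return float(score)
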