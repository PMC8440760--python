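"""Pair preprocessing: intensity normalisation, breast-border removal and
gamma correction.

Both images of a temporal pair are processed with identical parameters so
that the later subtraction compares like with like.  Pixels outside the
breast mask are set to zero, confining registration forces and contrast
statistics to tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io import MammoImage


class SegmentationError(RuntimeError):
    """No breast foreground found."""


@dataclass
class BreastMask:
    """Boolean breast-region mask congruent with the image."""

    mask: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def normalise(img: MammoImage) -> MammoImage:
    """Min-max rescale to [0, 1]; constant images map to all zeros."""
    px = np.asarray(img.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def segment_breast(
    img: MammoImage,
    fg_threshold: float = 0.05,
    border_margin_px: int = 4,
    close_radius: int = 3,
) -> BreastMask:
    """Segment the breast as the largest bright connected component.

    Thresholds the normalised image at ``fg_threshold``, closes small gaps,
    clears a fixed margin around the frame (dropping edge labels and scanner
    artifacts), and keeps the largest 8-connected component with holes
    filled.
    """
    px = np.asarray(img.pixels, dtype=np.float64)
    fg = px > fg_threshold
    if close_radius > 0:
        fg = morphology.closing(fg, morphology.disk(close_radius))
    if border_margin_px > 0:
        m = border_margin_px
        fg[:m, :] = False
        fg[-m:, :] = False
        fg[:, :m] = False
        fg[:, -m:] = False
    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))
    if n == 0:
        raise SegmentationError("no foreground pixels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    return BreastMask(mask=mask)


def gamma_correct(img: MammoImage, gamma: float = 2.0) -> MammoImage:
    """Pixelwise power-law transform ``out = in**gamma`` on a unit-interval
    image; gamma > 1 suppresses dim background, gamma < 1 lifts it."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    px = np.asarray(img.pixels, dtype=np.float64)
    return img.with_pixels(np.power(np.clip(px, 0.0, 1.0), gamma))


def preprocess(
    img: MammoImage,
    gamma: float = 2.0,
    fg_threshold: float = 0.05,
    border_margin_px: int = 4,
) -> tuple[MammoImage, BreastMask]:
    """Full preprocessing chain: normalise, segment, gamma-correct, zero the
    background.  Returns the processed image and the breast mask."""
    norm = normalise(img)
    mask = segment_breast(norm, fg_threshold=fg_threshold, border_margin_px=border_margin_px)
    out = gamma_correct(norm, gamma=gamma)
    px = out.pixels.copy()
    px[~mask.mask] = 0.0
    return out.with_pixels(px), mask
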