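"""Temporal subtraction of the registered prior from the recent view.

The difference image keeps only positive change (new findings are brighter
than their local background; darkening is not a detection signal here).
Background suppression is quantified by the contrast ratio — maximum over
mean intensity inside the breast mask — and by the percentage reduction of
mean intensity.  Removal accounting scores how many unchanged (old)
microcalcifications were eliminated by subtraction and checks that no new
finding was.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import MammoImage
from .phantom import TruthPoint
from .preprocess import BreastMask


@dataclass
class SubtractionResult:
    diff: np.ndarray
    contrast_ratio_recent: float
    contrast_ratio_diff: float
    intensity_reduction_pct: float


@dataclass
class RemovalStats:
    """Per-image accounting of microcalcification elimination.

    ``overlap_pct`` is the share of prior-round microcalcifications that
    subtraction removed; ``reduction_pct`` is the same count as a share of
    all recent-round microcalcifications.
    """

    n_recent_mcs: int
    n_prior_mcs: int
    n_overlapping: int
    n_new_removed: int = 0

    @property
    def overlap_pct(self) -> float:
        if self.n_prior_mcs == 0:
            return float("nan")
        return 100.0 * self.n_overlapping / self.n_prior_mcs

    @property
    def reduction_pct(self) -> float:
        if self.n_recent_mcs == 0:
            return float("nan")
        return 100.0 * self.n_overlapping / self.n_recent_mcs


def contrast_ratio(arr: np.ndarray, mask: np.ndarray) -> float:
    """Maximum over mean intensity within the mask; NaN when the masked
    mean is zero (fully cancelled image)."""
    vals = arr[mask]
    mean = float(vals.mean())
    if mean == 0.0:
        return float("nan")
    return float(vals.max()) / mean


def subtract(
    recent: MammoImage | np.ndarray,
    prior_warped: MammoImage | np.ndarray,
    mask: BreastMask | np.ndarray,
) -> SubtractionResult:
    """diff = max(recent - prior_warped, 0) inside the breast mask.

    Also reports contrast ratios of the recent and difference images and
    the percentage drop in mean intensity, all over mask pixels only.
    """
    r = np.asarray(recent.pixels if isinstance(recent, MammoImage) else recent, dtype=np.float64)
    p = np.asarray(
        prior_warped.pixels if isinstance(prior_warped, MammoImage) else prior_warped,
        dtype=np.float64,
    )
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    if r.shape != p.shape or r.shape != m.shape:
        raise ValueError("recent/prior/mask shapes must match")
    if not m.any():
        raise ValueError("empty breast mask")
    diff = np.where(m, np.clip(r - p, 0.0, None), 0.0)
    mean_recent = float(r[m].mean())
    mean_diff = float(diff[m].mean())
    reduction = 100.0 * (1.0 - mean_diff / mean_recent) if mean_recent > 0 else float("nan")
    return SubtractionResult(
        diff=diff,
        contrast_ratio_recent=contrast_ratio(r, m),
        contrast_ratio_diff=contrast_ratio(diff, m),
        intensity_reduction_pct=reduction,
    )


def _window(arr: np.ndarray, row: int, col: int, half: int) -> np.ndarray:
    r0, r1 = max(row - half, 0), min(row + half + 1, arr.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, arr.shape[1])
    return arr[r0:r1, c0:c1]


def removal_stats(
    diff: np.ndarray,
    recent: MammoImage | np.ndarray,
    truth: Sequence[TruthPoint],
    residual_frac_threshold: float = 0.5,
    window_half_px: int = 5,
) -> RemovalStats:
    """Score elimination of old microcalcifications in a subtracted image.

    A microcalcification counts as removed when its residual peak in
    ``diff``, within a small window around its annotated centre, falls
    below ``residual_frac_threshold`` times its contrast in the recent
    image (window peak above the window median, which estimates the local
    background).  New findings are scored by the same rule so accidental
    removal of a new (suspicious-analogue) spot is detected.
    """
    r = np.asarray(recent.pixels if isinstance(recent, MammoImage) else recent, dtype=np.float64)
    diff = np.asarray(diff, dtype=np.float64)
    n_recent = len(truth)
    n_prior = sum(1 for t in truth if t.status == "old")
    n_removed_old = 0
    n_removed_new = 0
    for t in truth:
        row, col = t.annotation.y, t.annotation.x
        win = _window(r, row, col, window_half_px)
        contrast_recent = float(win.max() - np.median(win))
        residual = float(_window(diff, row, col, window_half_px).max())
        removed = residual < residual_frac_threshold * max(contrast_recent, 1e-12)
        if t.status == "old" and removed:
            n_removed_old += 1
        elif t.status == "new" and removed:
            n_removed_new += 1
    return RemovalStats(
        n_recent_mcs=n_recent,
        n_prior_mcs=n_prior,
        n_overlapping=n_removed_old,
        n_new_removed=n_removed_new,
    )
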