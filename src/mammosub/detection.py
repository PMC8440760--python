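"""Candidate microcalcification segmentation and ground-truth matching.

The detection chain is: local range filtering (max minus min over a small
window, which lights up small bright structures), global thresholding to a
binary map, morphological cleaning (bridge 1-2 px gaps, drop specks below a
minimum area), and 8-connected component labelling.  Candidates are scored
against point annotations by optimal one-to-one assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io import MammoImage


@dataclass
class CandidateRegion:
    """One connected segment hypothesised to be a microcalcification."""

    mask: np.ndarray  # boolean, over the bounding box
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    source: str = "subtracted"  # or "recent_only"
    patient_id: str = ""
    view: str = ""


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)  # (candidate idx, annotation idx)


def range_filter(img: MammoImage | np.ndarray, window: int = 3) -> np.ndarray:
    """Local max minus local min over a window x window neighbourhood
    (borders replicated)."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    arr = np.asarray(img.pixels if isinstance(img, MammoImage) else img, dtype=np.float64)
    mx = ndimage.maximum_filter(arr, size=window, mode="nearest")
    mn = ndimage.minimum_filter(arr, size=window, mode="nearest")
    return mx - mn


def binarise(img: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a unit-interval image: pixel >= threshold -> True."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(img, dtype=np.float64) >= threshold


def morph_clean(
    binary: np.ndarray,
    min_area: int = 4,
    gap_close_radius: int = 1,
    source: str = "subtracted",
    patient_id: str = "",
    view: str = "",
) -> list[CandidateRegion]:
    """Bridge small gaps, drop sub-minimum components, label candidates.

    Closing with a disc of ``gap_close_radius`` merges fragments separated
    by hairline gaps; components with fewer than ``min_area`` pixels are
    discarded as noise specks.  The area filter is applied to the original
    (pre-closing) support of each component so closing does not inflate
    speck areas past the cut.
    """
    binary = np.asarray(binary, dtype=bool)
    closed = binary
    if gap_close_radius > 0:
        closed = morphology.closing(binary, morphology.disk(gap_close_radius))
        closed |= binary
    labels, n = ndimage.label(closed, structure=np.ones((3, 3)))
    if n == 0:
        return []
    orig_areas = ndimage.sum_labels(binary.astype(np.int64), labels, index=np.arange(1, n + 1))
    out: list[CandidateRegion] = []
    slices = ndimage.find_objects(labels)
    for lab, (area, sl) in enumerate(zip(orig_areas, slices), start=1):
        if area < min_area or sl is None:
            continue
        comp = labels[sl] == lab
        rows, cols = np.nonzero(comp)
        r0, c0 = sl[0].start, sl[1].start
        out.append(
            CandidateRegion(
                mask=comp,
                bbox=(r0, c0, sl[0].stop, sl[1].stop),
                centroid=(r0 + float(rows.mean()), c0 + float(cols.mean())),
                area_px=int(comp.sum()),
                source=source,
                patient_id=patient_id,
                view=view,
            )
        )
    return out


def detect(
    img: MammoImage | np.ndarray,
    mask: Optional[np.ndarray] = None,
    threshold: float = 0.2,
    window: int = 3,
    min_area: int = 4,
    gap_close_radius: int = 1,
    source: str = "subtracted",
) -> list[CandidateRegion]:
    """Full detection chain on one (subtracted or raw recent) image."""
    rng_img = range_filter(img, window=window)
    binary = binarise(rng_img, threshold)
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    return morph_clean(binary, min_area=min_area, gap_close_radius=gap_close_radius, source=source)


def _point_in_candidate(cand: CandidateRegion, row: float, col: float) -> bool:
    r0, c0, r1, c1 = cand.bbox
    ri, ci = int(round(row)), int(round(col))
    if not (r0 <= ri < r1 and c0 <= ci < c1):
        return False
    return bool(cand.mask[ri - r0, ci - c0])


def match_candidates(
    cands: Sequence[CandidateRegion],
    annotations: Sequence,
    tol_px: float = 8.0,
) -> MatchResult:
    """Optimal one-to-one matching of candidates to point annotations.

    A (candidate, annotation) pair is eligible when the point falls inside
    the candidate's mask or within ``tol_px`` of its centroid.  The
    matching maximises the number of eligible pairs and, among those,
    minimises the total centre distance (Hungarian assignment with a
    prohibitive cost on ineligible pairs) — deterministic, and identical to
    exhaustive assignment on any instance.  Annotations may be
    :class:`~mammosub.io.Annotation` or any object with y/x attributes.
    """
    from scipy.optimize import linear_sum_assignment

    pts = [(float(a.y), float(a.x)) for a in annotations]
    if not cands or not pts:
        return MatchResult(tp=0, fp=len(cands), fn=len(pts), pairs=[])
    dist = np.zeros((len(cands), len(pts)))
    eligible = np.zeros_like(dist, dtype=bool)
    for ci, cand in enumerate(cands):
        cr, cc = cand.centroid
        for ai, (ar, ac) in enumerate(pts):
            d = float(np.hypot(cr - ar, cc - ac))
            dist[ci, ai] = d
            eligible[ci, ai] = d <= tol_px or _point_in_candidate(cand, ar, ac)
    big = dist.max() * (dist.size + 1) + 1.0
    cost = np.where(eligible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(ci), int(ai)) for ci, ai in zip(rows, cols) if eligible[ci, ai]]
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(cands) - tp, fn=len(pts) - tp, pairs=pairs)


def optimise_threshold(
    labelled_images: Sequence[tuple[np.ndarray, Optional[np.ndarray], Sequence]],
    grid: Sequence[float],
    tol_px: float = 8.0,
    fp_weight: float = 1.0,
    **detect_kwargs,
) -> float:
    """Pick the binarisation threshold maximising tp - fp_weight * fp over a
    labelled development set, via the full detect-and-match path.

    ``labelled_images`` holds (image, mask, annotations) triples.  Ties are
    broken toward the higher threshold.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    best_t, best_obj = None, -np.inf
    for t in sorted(grid):
        obj = 0.0
        for img, mask, anns in labelled_images:
            cands = detect(img, mask=mask, threshold=t, **detect_kwargs)
            m = match_candidates(cands, anns, tol_px=tol_px)
            obj += m.tp - fp_weight * m.fp
        if obj >= best_obj:
            best_obj, best_t = obj, t
    return best_t


def match_candidates_bruteforce(
    cands: Sequence[CandidateRegion], annotations: Sequence, tol_px: float = 8.0
) -> int:
    """Maximum-cardinality one-to-one matching by exhaustive assignment;
    exponential, only for cross-checking on tiny instances."""
    pts = [(float(a.y), float(a.x)) for a in annotations]
    eligible = np.zeros((len(cands), len(pts)), dtype=bool)
    for ci, cand in enumerate(cands):
        cr, cc = cand.centroid
        for ai, (ar, ac) in enumerate(pts):
            d = float(np.hypot(cr - ar, cc - ac))
            eligible[ci, ai] = d <= tol_px or _point_in_candidate(cand, ar, ac)
    n_c, n_a = len(cands), len(pts)
    best = 0
    idx = list(range(n_a)) + [-1] * max(0, n_c - n_a)
    for perm in set(permutations(idx, n_c)):
        tp = sum(1 for ci, ai in enumerate(perm) if ai >= 0 and eligible[ci, ai])
        best = max(best, tp)
    return best
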