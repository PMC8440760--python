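"""Non-rigid Demons registration of the prior view onto the recent view.

Classic intensity-driven Demons: at every pixel the displacement increment
is

    du = -(m_w - f) * grad(f) / (|grad(f)|^2 + (m_w - f)^2)

where ``f`` is the fixed (recent) image and ``m_w`` the moving (prior)
image warped by the current field.  The increment is Gaussian-smoothed
("fluid" regularisation), added to the field, and the field itself is
Gaussian-smoothed ("diffusion" regularisation).  The scheme runs
coarse-to-fine over an image pyramid, with displacements damped towards
zero outside the breast mask where there is no intensity information to
constrain them.

All fields use backward (pull) convention: ``warped(p) = moving(p + d(p))``
with bilinear interpolation, so a converged field maps prior-frame content
into the geometry of the recent frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import MammoImage


@dataclass
class DemonsParams:
    """Tunables for the Demons solver (all lengths in pixels at full
    resolution).

    sigma_fluid    smoothing of each update before it is applied
    sigma_diffusion  smoothing of the accumulated field every iteration
    pyramid_factors  coarse-to-fine downsampling factors
    iterations     per pyramid level
    step_cap       upper bound on the per-iteration displacement increment
    stop_rel_improvement / stop_window  early stop when the mean squared
                   difference improves by less than the given relative
                   amount over the window
    """

    sigma_fluid: float = 1.0
    sigma_diffusion: float = 4.0
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    iterations: int = 80
    step_cap: float = 2.0
    stop_rel_improvement: float = 1e-4
    stop_window: int = 10
    intensity_floor: float = 1e-9
    intensity_match: bool = True
    gain_sigma: float = 32.0
    border_px: int = 8
    force_sigma: float = 1.0
    symmetric_forces: bool = True


@dataclass
class DeformationField:
    """Per-pixel 2-D displacement (pixels), backward convention."""

    dy: np.ndarray
    dx: np.ndarray
    level_count: int = 1
    final_metric: float = float("nan")
    level_metrics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=np.float64)
        self.dx = np.asarray(self.dx, dtype=np.float64)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy/dx shape mismatch")
        if not (np.isfinite(self.dy).all() and np.isfinite(self.dx).all()):
            raise ValueError("deformation field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    def save(self, path) -> None:
        np.save(path, np.stack([self.dy, self.dx]))

    @classmethod
    def load(cls, path) -> "DeformationField":
        arr = np.load(path)
        return cls(dy=arr[0], dx=arr[1])


def warp(img: MammoImage | np.ndarray, field: DeformationField) -> MammoImage | np.ndarray:
    """Backward-warp an image: ``out(p) = img(p + d(p))``, bilinear, with
    out-of-bounds samples set to 0."""
    arr = img.pixels if isinstance(img, MammoImage) else np.asarray(img)
    if arr.shape != field.shape:
        raise ValueError(f"image shape {arr.shape} != field shape {field.shape}")
    rows, cols = np.meshgrid(
        np.arange(arr.shape[0], dtype=np.float64),
        np.arange(arr.shape[1], dtype=np.float64),
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(arr, dtype=np.float64),
        [rows + field.dy, cols + field.dx],
        order=1,
        mode="constant",
        cval=0.0,
    )
    if isinstance(img, MammoImage):
        return img.with_pixels(out)
    return out


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr, sigma=factor / 2.0)
    return sm[::factor, ::factor]


def _resize_field(comp: np.ndarray, shape: tuple[int, int], scale: float) -> np.ndarray:
    zoom = (shape[0] / comp.shape[0], shape[1] / comp.shape[1])
    return ndimage.zoom(comp, zoom, order=1) * scale


def _mean_sq_diff(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray]) -> float:
    d = a - b
    if mask is not None:
        d = d[mask]
    return float(np.mean(d * d))


def match_intensity(
    moving: np.ndarray,
    fixed: np.ndarray,
    mask: Optional[np.ndarray] = None,
    gain_sigma: float = 32.0,
) -> np.ndarray:
    """Harmonise the moving image's intensities to the fixed image before
    registration: a low-pass gain-ratio correction absorbs smooth
    multiplicative drift between acquisitions, then exact histogram matching
    removes any residual monotone intensity mismatch (e.g. from per-image
    normalisation).  Intensity differences the Demons forces cannot explain
    by deformation would otherwise be absorbed into spurious flows.
    """
    m = np.ones_like(fixed, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    out = moving.astype(np.float64).copy()
    if gain_sigma > 0:
        eps = 1e-3
        sm = np.maximum(ndimage.gaussian_filter(m.astype(np.float64), gain_sigma), eps)
        lp_f = ndimage.gaussian_filter(np.where(m, fixed, 0.0), gain_sigma) / sm
        lp_m = ndimage.gaussian_filter(np.where(m, out, 0.0), gain_sigma) / sm
        gain = np.clip(lp_f / np.maximum(lp_m, eps), 0.5, 2.0)
        out = np.where(m, out * gain, out)
    src = out[m]
    ref = fixed[m]
    order = np.argsort(src, kind="stable")
    quantile = np.empty_like(src)
    quantile[order] = np.linspace(0.0, 1.0, src.size)
    out[m] = np.quantile(ref, quantile)
    return out


def demons_register(
    fixed: MammoImage | np.ndarray,
    moving: MammoImage | np.ndarray,
    params: Optional[DemonsParams] = None,
    mask: Optional[np.ndarray] = None,
) -> DeformationField:
    """Register ``moving`` (prior) onto ``fixed`` (recent).

    Returns the converged deformation field together with the final mean
    squared intensity difference; the metric never ends above its starting
    value at any pyramid level (the best-so-far field is kept).  The metric
    is evaluated inside the breast mask when one is given, else away from a
    small frame border where warping pulls in out-of-bounds zeros.
    """
    p = params or DemonsParams()
    f_full = np.asarray(fixed.pixels if isinstance(fixed, MammoImage) else fixed, dtype=np.float64)
    m_full = np.asarray(moving.pixels if isinstance(moving, MammoImage) else moving, dtype=np.float64)
    if f_full.shape != m_full.shape:
        raise ValueError(f"shape mismatch: fixed {f_full.shape} vs moving {m_full.shape}")
    if not (np.isfinite(f_full).all() and np.isfinite(m_full).all()):
        raise ValueError("images must be finite")

    mask_full = None
    soft_full = None
    metric_mask_full = np.zeros_like(f_full, dtype=np.float64)
    b = p.border_px
    metric_mask_full[b:-b, b:-b] = 1.0
    if mask is not None:
        mask_full = np.asarray(mask, dtype=bool)
        if mask_full.shape != f_full.shape:
            raise ValueError("mask shape mismatch")
        soft_full = ndimage.gaussian_filter(mask_full.astype(np.float64), sigma=4.0)
        metric_mask_full = mask_full.astype(np.float64)

    if p.intensity_match:
        m_full = match_intensity(m_full, f_full, mask_full, gain_sigma=p.gain_sigma)

    dy = dx = None
    level_metrics: list[tuple[float, float]] = []
    for level, factor in enumerate(p.pyramid_factors):
        f = _downsample(f_full, factor)
        m = _downsample(m_full, factor)
        soft = None
        msk = _downsample(metric_mask_full, factor) > 0.5
        if mask_full is not None:
            soft = _downsample(soft_full, factor)
        if dy is None:
            dy = np.zeros_like(f)
            dx = np.zeros_like(f)
        else:
            prev = p.pyramid_factors[level - 1]
            scale = prev / factor
            dy = _resize_field(dy, f.shape, scale)
            dx = _resize_field(dx, f.shape, scale)

        if p.force_sigma > 0:
            fs = ndimage.gaussian_filter(f, p.force_sigma)
            ms = ndimage.gaussian_filter(m, p.force_sigma)
        else:
            fs, ms = f, m
        gy, gx = np.gradient(fs)
        fld = DeformationField(dy=dy, dx=dx)
        initial = _mean_sq_diff(warp(m, fld), f, msk)
        best = initial
        best_dy, best_dx = dy.copy(), dx.copy()
        since_improved = 0
        for _ in range(p.iterations):
            mw = warp(ms, DeformationField(dy=dy, dx=dx))
            diff = mw - fs
            if p.symmetric_forces:
                my_, mx_ = np.gradient(mw)
                jy, jx = 0.5 * (gy + my_), 0.5 * (gx + mx_)
            else:
                jy, jx = gy, gx
            denom = jy * jy + jx * jx + diff * diff
            with np.errstate(divide="ignore", invalid="ignore"):
                uy = np.where(denom > p.intensity_floor, -diff * jy / denom, 0.0)
                ux = np.where(denom > p.intensity_floor, -diff * jx / denom, 0.0)
            mag = np.hypot(uy, ux)
            over = mag > p.step_cap
            if over.any():
                sc = np.where(over, p.step_cap / np.maximum(mag, 1e-12), 1.0)
                uy *= sc
                ux *= sc
            if p.sigma_fluid > 0:
                uy = ndimage.gaussian_filter(uy, p.sigma_fluid)
                ux = ndimage.gaussian_filter(ux, p.sigma_fluid)
            dy = dy + uy
            dx = dx + ux
            if p.sigma_diffusion > 0:
                dy = ndimage.gaussian_filter(dy, p.sigma_diffusion)
                dx = ndimage.gaussian_filter(dx, p.sigma_diffusion)
            if soft is not None:
                dy = dy * soft
                dx = dx * soft
            metric = _mean_sq_diff(warp(m, DeformationField(dy=dy, dx=dx)), f, msk)
            if metric < best * (1.0 - p.stop_rel_improvement):
                best = metric
                best_dy, best_dx = dy.copy(), dx.copy()
                since_improved = 0
            else:
                if metric < best:
                    best = metric
                    best_dy, best_dx = dy.copy(), dx.copy()
                since_improved += 1
                if since_improved >= p.stop_window:
                    break
        dy, dx = best_dy, best_dx
        level_metrics.append((initial, best))

    return DeformationField(
        dy=dy,
        dx=dx,
        level_count=len(p.pyramid_factors),
        final_metric=level_metrics[-1][1],
        level_metrics=level_metrics,
    )
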