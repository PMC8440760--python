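"""Synthetic temporally sequential mammogram pairs with known ground truth.

A phantom pair emulates the structure of a two-round screening dataset:

* a half-elliptical breast region over a dark background, filled with
  smooth multi-scale blob texture standing in for fibroglandular tissue;
* *old benign* microcalcifications present in both rounds — larger, round,
  spatially scattered bright spots;
* *new* microcalcifications present only in the recent round; the
  suspicious-analogue ones are smaller, irregular (randomly perturbed
  ellipses) and tightly clustered, encoding the morphology/distribution
  cues radiologists use;
* the prior image is the recent image minus the new findings, deformed by
  a smooth random displacement field, with independent noise and a mild
  global intensity drift.

The generated ``true_field`` maps prior-frame content into the recent
frame (backward convention), i.e. ``warp(prior, true_field)`` reproduces
the clean recent-minus-new image up to interpolation error: the prior is
rendered through the numerically inverted field, so registration accuracy
can be scored against an exactly consistent ground truth.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import Annotation, Label, MammoImage, Round, View
from .registration import DeformationField, warp


class GenerationError(RuntimeError):
    """Requested microcalcification layout does not fit the breast mask."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic pair.

    Defaults are the package's standard desk-scale study conditions:
    512x416 frames (1/8 of a full-field digital mammogram), microcalcification
    contrast 0.35 above local background on the unit interval, benign radii
    2-4 px, a 6 px peak inter-round deformation and 1% additive noise.
    """

    height: int = 512
    width: int = 416
    n_old_benign: int = 6
    n_new_benign: int = 2
    n_new_suspicious: int = 5
    mc_amplitude: float = 0.35
    mc_radius_px: tuple[float, float] = (2.0, 4.0)
    deformation_amplitude_px: float = 6.0
    deformation_sigma_px: float = 16.0
    noise_sigma: float = 0.01
    drift_amplitude: float = 0.02
    n_clutter: int = 40
    clutter_amplitude: tuple[float, float] = (0.08, 0.35)
    clutter_radius_px: tuple[float, float] = (0.8, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_old_benign, self.n_new_benign, self.n_new_suspicious) < 0:
            raise ValueError("microcalcification counts must be >= 0")
        if self.deformation_amplitude_px < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if not (0.0 < self.mc_amplitude <= 1.0):
            raise ValueError("mc_amplitude must be in (0, 1]")


@dataclass
class TruthPoint:
    """Ground-truth microcalcification in the recent frame."""

    annotation: Annotation
    status: str  # "old" | "new"
    peak_recent: float = 0.0


@dataclass
class PhantomPair:
    recent: MammoImage
    prior: MammoImage
    truth: list[TruthPoint]
    true_field: DeformationField
    breast_mask: np.ndarray = dc_field(default=None)


def _breast_mask(h: int, w: int) -> np.ndarray:
    """Half-ellipse anchored on the left (chest-wall) edge."""
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, a, b = h / 2.0, 0.44 * h, 0.82 * w
    return ((rows - cy) / a) ** 2 + (cols / b) ** 2 <= 1.0


def _tissue_texture(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth multi-scale blob texture in roughly [0.15, 0.55]."""
    tex = np.zeros((h, w))
    for sigma, weight in ((4, 0.2), (8, 0.35), (16, 0.3), (32, 0.15)):
        layer = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        layer /= max(layer.std(), 1e-12)
        tex += weight * layer
    tex -= tex.min()
    tex /= max(tex.max(), 1e-12)
    return 0.15 + 0.40 * tex


def _round_spot(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Soft-edged disc profile in [0, 1], size odd."""
    half = int(np.ceil(radius)) + 2
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    r = np.hypot(yy, xx)
    edge = 0.7
    return np.clip((radius + edge - r) / edge, 0.0, 1.0)


def _irregular_spot(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Perturbed-ellipse profile: random axis ratio plus radial harmonics."""
    half = int(np.ceil(radius * 1.8)) + 2
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    ratio = rng.uniform(0.45, 0.8)
    r = np.hypot(u / 1.0, v / ratio)
    phi = np.arctan2(v, u)
    wobble = np.zeros_like(phi)
    for k in (2, 3, 5):
        wobble += rng.uniform(0.0, 0.18) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    r_eff = radius * (1.0 + wobble)
    edge = 0.6
    return np.clip((r_eff + edge - r) / edge, 0.0, 1.0)


def _stamp(img: np.ndarray, spot: np.ndarray, row: int, col: int, amp: float) -> None:
    h, w = img.shape
    sh, sw = spot.shape
    r0, c0 = row - sh // 2, col - sw // 2
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + sh, h), min(c0 + sw, w)
    if re <= rs or ce <= cs:
        return
    img[rs:re, cs:ce] += amp * spot[rs - r0 : re - r0, cs - c0 : ce - c0]


def _sample_positions(
    mask: np.ndarray,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    avoid: Optional[list[tuple[int, int]]] = None,
    avoid_dist: float = 0.0,
    max_tries: int = 4000,
) -> list[tuple[int, int]]:
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise GenerationError("empty placement region")
    placed: list[tuple[int, int]] = []
    avoid = avoid or []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n} spots with spacing {min_dist:.0f}px in the mask"
            )
        tries += 1
        r, c = coords[rng.integers(len(coords))]
        if any(np.hypot(r - pr, c - pc) < min_dist for pr, pc in placed):
            continue
        if any(np.hypot(r - pr, c - pc) < avoid_dist for pr, pc in avoid):
            continue
        placed.append((int(r), int(c)))
    return placed


def _random_smooth_field(
    shape: tuple[int, int], amplitude: float, sigma: float, rng: np.random.Generator
) -> DeformationField:
    dy = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    dx = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = max(np.hypot(dy, dx).max(), 1e-12)
    return DeformationField(dy=dy * amplitude / peak, dx=dx * amplitude / peak)


def invert_field(f: DeformationField, iterations: int = 20) -> DeformationField:
    """Fixed-point numerical inverse: e(q) = -f(q + e(q)).

    For smooth fields this converges quickly and makes the generated pair
    exactly consistent: backward-warping the prior by ``f`` recovers the
    clean image the prior was rendered from.
    """
    ey = np.zeros_like(f.dy)
    ex = np.zeros_like(f.dx)
    rows, cols = np.meshgrid(
        np.arange(f.shape[0], dtype=np.float64),
        np.arange(f.shape[1], dtype=np.float64),
        indexing="ij",
    )
    for _ in range(iterations):
        fy = ndimage.map_coordinates(f.dy, [rows + ey, cols + ex], order=1, mode="nearest")
        fx = ndimage.map_coordinates(f.dx, [rows + ey, cols + ex], order=1, mode="nearest")
        ey, ex = -fy, -fx
    return DeformationField(dy=ey, dx=ex)


def make_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one recent/prior pair with ground truth.

    The recent image is (tissue + old spots + new spots); the prior is
    (tissue + old spots) pushed through the inverse of ``true_field``, with
    independent noise on both rounds and a mild multiplicative drift on the
    prior.  With zero deformation, noise and drift the prior equals the
    recent image minus exactly the new findings' rendered spots.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _breast_mask(h, w)

    base = np.where(mask, _tissue_texture(h, w, rng), 0.02)

    # static fine clutter: small dim specks present in BOTH rounds, standing
    # in for the microcalcification-mimicking fine structure (fibre
    # crossings, tiny benign densities) that drives false positives in
    # single-image detection; being unchanged, subtraction cancels them
    clutter_region = ndimage.binary_erosion(mask, iterations=6)
    if spec.n_clutter > 0:
        coords = np.argwhere(clutter_region)
        for _ in range(spec.n_clutter):
            r, c = coords[rng.integers(len(coords))]
            radius = rng.uniform(*spec.clutter_radius_px)
            amp = rng.uniform(*spec.clutter_amplitude)
            _stamp(base, _round_spot(radius, rng), int(r), int(c), amp)

    r_lo, r_hi = spec.mc_radius_px
    interior = ndimage.binary_erosion(mask, iterations=int(10 * r_hi))

    # benign spots scattered (spacing ~ a cluster diameter apart), the
    # suspicious-analogue cluster confined to a disc of radius 10 x radius
    cluster_r = 10.0 * r_hi
    benign_spacing = 2.0 * cluster_r
    n_benign = spec.n_old_benign + spec.n_new_benign
    benign_pos = _sample_positions(interior, n_benign, benign_spacing, rng)
    old_pos = benign_pos[: spec.n_old_benign]
    new_benign_pos = benign_pos[spec.n_old_benign :]

    sus_pos: list[tuple[int, int]] = []
    if spec.n_new_suspicious > 0:
        centre = _sample_positions(
            interior, 1, 0.0, rng, avoid=benign_pos, avoid_dist=1.5 * cluster_r
        )[0]
        disc = np.zeros_like(mask)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        disc[(np.hypot(rr - centre[0], cc - centre[1]) <= cluster_r) & interior] = True
        sus_pos = _sample_positions(disc, spec.n_new_suspicious, 2.5 * r_lo, rng)

    clean_prior = base.copy()
    truth: list[TruthPoint] = []

    def add_spot(img_arr, pos, label, status, irregular, radius_scale=1.0):
        radius = rng.uniform(r_lo, r_hi) * radius_scale
        amp = spec.mc_amplitude * rng.uniform(0.85, 1.0)
        spot = _irregular_spot(radius, rng) if irregular else _round_spot(radius, rng)
        _stamp(img_arr, spot, pos[0], pos[1], amp)
        truth.append(
            TruthPoint(
                annotation=Annotation(
                    patient_id="phantom",
                    view=View.CC,
                    round=Round.RECENT,
                    x=pos[1],
                    y=pos[0],
                    label=label,
                ),
                status=status,
            )
        )

    for pos in old_pos:
        add_spot(clean_prior, pos, Label.BENIGN, "old", irregular=False)
    recent_clean = clean_prior.copy()
    for pos in new_benign_pos:
        add_spot(recent_clean, pos, Label.BENIGN, "new", irregular=False)
    for pos in sus_pos:
        add_spot(recent_clean, pos, Label.SUSPICIOUS, "new", irregular=True, radius_scale=0.6)

    for t in truth:
        t.peak_recent = float(recent_clean[t.annotation.y, t.annotation.x])

    if spec.deformation_amplitude_px > 0:
        true_field = _random_smooth_field(
            (h, w), spec.deformation_amplitude_px, spec.deformation_sigma_px, rng
        )
        inv = invert_field(true_field)
        prior_arr = warp(clean_prior, inv)
    else:
        true_field = DeformationField(dy=np.zeros((h, w)), dx=np.zeros((h, w)))
        prior_arr = clean_prior.copy()

    recent_arr = recent_clean.copy()
    if spec.drift_amplitude > 0:
        ramp = np.linspace(-1.0, 1.0, w)[None, :]
        prior_arr = prior_arr * (1.0 + spec.drift_amplitude * ramp)
    if spec.noise_sigma > 0:
        recent_arr = recent_arr + rng.normal(0.0, spec.noise_sigma, (h, w))
        prior_arr = prior_arr + rng.normal(0.0, spec.noise_sigma, (h, w))
    recent_arr = np.clip(recent_arr, 0.0, 1.0)
    prior_arr = np.clip(prior_arr, 0.0, 1.0)

    recent = MammoImage(recent_arr, patient_id="phantom", view=View.CC, round=Round.RECENT)
    prior = MammoImage(prior_arr, patient_id="phantom", view=View.CC, round=Round.PRIOR)
    return PhantomPair(
        recent=recent, prior=prior, truth=truth, true_field=true_field, breast_mask=mask
    )


def make_feature_cohort(
    n_patients: int,
    class_separation: float,
    seed: int,
    n_features: int = 96,
    samples_per_patient: tuple[int, int] = (3, 6),
    patient_effect_sd: float = 0.5,
):
    """Labelled synthetic feature table for classifier-stage tests.

    Patients are split half/half into two classes whose 96-dimensional
    Gaussian means differ by ``class_separation`` within-class standard
    deviations along a random direction; each patient contributes several
    vectors around a patient-specific offset so grouped cross-validation has
    real structure to respect.

    Returns ``(X, y, groups)``: feature matrix, binary labels (1 =
    suspicious-class patient) and patient-id strings.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if class_separation < 0:
        raise ValueError("class_separation must be >= 0")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    offset = 0.5 * class_separation * direction

    X_rows, y_rows, g_rows = [], [], []
    for i in range(n_patients):
        cls = i % 2
        mu = offset if cls == 1 else -offset
        patient_shift = patient_effect_sd * rng.standard_normal(n_features)
        n_samples = int(rng.integers(samples_per_patient[0], samples_per_patient[1] + 1))
        for _ in range(n_samples):
            X_rows.append(mu + patient_shift + rng.standard_normal(n_features))
            y_rows.append(cls)
            g_rows.append(f"P{i:03d}")
    return np.asarray(X_rows), np.asarray(y_rows), np.asarray(g_rows)
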