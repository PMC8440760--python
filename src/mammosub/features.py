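"""Per-candidate feature extraction: 12 shape, 12 first-order intensity and
72 grey-level co-occurrence (GLCM) texture features, 96 in total.

The GLCM block follows the classic Haralick construction: the patch around
a candidate is quantised to a fixed number of grey levels and co-occurrence
matrices are accumulated at four angles (0, 45, 90, 135 degrees) and three
offsets (5, 15, 25 px).  Twelve texture properties are computed on each of
the 12 matrices and summarised as the mean and standard deviation across
the four angles, separately per offset: 12 properties x 3 offsets x 2
statistics = 72 features.  Matrices are normalised to sum 1 and are NOT
symmetrised.

Feature names and their order are a fixed, versioned schema
(:data:`FEATURE_NAMES`) so tables are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import measure

from .detection import CandidateRegion

GLCM_ANGLES = (0, 45, 90, 135)
GLCM_OFFSETS = (5, 15, 25)
GLCM_LEVELS = 32
MIN_PATCH = 32  # patches zero-padded to at least this size so every offset fits

# displacement (drow, dcol) per angle, standard Haralick convention
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

SHAPE_FEATURES = [
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "equivalent_diameter",
    "circularity",
    "convex_area",
    "orientation",
]

FIRSTORDER_FEATURES = [
    "mean",
    "std",
    "min",
    "max",
    "median",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "range",
    "p10",
    "p90",
]

GLCM_PROPERTIES = [
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "dissimilarity",
    "entropy",
    "max_probability",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
]


def _glcm_feature_names() -> list[str]:
    names = []
    for off in GLCM_OFFSETS:
        for prop in GLCM_PROPERTIES:
            for stat in ("mean", "std"):
                names.append(f"glcm_{prop}_d{off}_{stat}")
    return names


FEATURE_NAMES: list[str] = (
    [f"shape_{n}" for n in SHAPE_FEATURES]
    + [f"intensity_{n}" for n in FIRSTORDER_FEATURES]
    + _glcm_feature_names()
)
N_FEATURES = len(FEATURE_NAMES)  # 96
N_GLCM_FEATURES = len(_glcm_feature_names())  # 72


class FeatureError(RuntimeError):
    pass


@dataclass
class FeatureVector:
    """The 96 named per-candidate features, in schema order."""

    values: dict[str, float]
    patient_id: str = ""
    candidate: CandidateRegion | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=np.float64)


def quantise(patch: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantise a unit-interval patch to integer grey levels 0..levels-1."""
    q = np.floor(np.clip(patch, 0.0, 1.0) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def glcm(
    patch: np.ndarray,
    levels: int = GLCM_LEVELS,
    angle: int = 0,
    offset: int = 5,
) -> np.ndarray:
    """Grey-level co-occurrence matrix of a quantised patch.

    ``patch`` must already hold integer levels in [0, levels).  Counts pairs
    (patch[p], patch[p + step*offset]) over every in-bounds position, where
    the step follows the standard angle convention (0 deg: east; 45: NE;
    90: north; 135: NW in image coordinates).  Returns the matrix
    normalised to sum 1, unsymmetrised.
    """
    if angle not in _ANGLE_STEPS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_STEPS)}, got {angle}")
    patch = np.asarray(patch)
    h, w = patch.shape
    if offset >= min(h, w):
        raise ValueError(f"offset {offset} >= patch dimension {min(h, w)}")
    dr, dc = _ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = patch[r0:r1, c0:c1].ravel()
    dst = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(src * levels + dst, minlength=levels * levels).reshape(levels, levels)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at this offset")
    return counts.astype(np.float64) / total


def glcm_properties(P: np.ndarray) -> dict[str, float]:
    """Twelve Haralick-style texture properties of one normalised GLCM."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    eps = 1e-12

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_i = float((i * px).sum())
    mu_j = float((i * py).sum())
    sd_i = float(np.sqrt(((i - mu_i) ** 2 * px).sum()))
    sd_j = float(np.sqrt(((i - mu_j) ** 2 * py).sum()))

    diff = ii - jj
    contrast = float((P * diff**2).sum())
    dissim = float((P * np.abs(diff)).sum())
    homog = float((P / (1.0 + diff**2)).sum())
    energy = float((P * P).sum())
    entropy = float(-(P[P > eps] * np.log2(P[P > eps])).sum())
    max_prob = float(P.max())
    if sd_i > eps and sd_j > eps:
        correlation = float((P * (ii - mu_i) * (jj - mu_j)).sum() / (sd_i * sd_j))
    else:
        correlation = 1.0  # constant patch: degenerate, perfectly correlated

    # sum / difference distributions p_{x+y}, p_{|x-y|}
    ksum = np.arange(2 * L - 1)
    p_sum = np.bincount((ii + jj).ravel().astype(np.int64), weights=P.ravel(), minlength=2 * L - 1)
    kdiff = np.arange(L)
    p_diff = np.bincount(
        np.abs(diff).ravel().astype(np.int64), weights=P.ravel(), minlength=L
    )
    sum_avg = float((ksum * p_sum).sum())
    sum_var = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-(p_sum[p_sum > eps] * np.log2(p_sum[p_sum > eps])).sum())
    diff_avg = float((kdiff * p_diff).sum())
    diff_var = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    diff_ent = float(-(p_diff[p_diff > eps] * np.log2(p_diff[p_diff > eps])).sum())

    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homog,
        "dissimilarity": dissim,
        "entropy": entropy,
        "max_probability": max_prob,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "difference_variance": diff_var,
        "difference_entropy": diff_ent,
    }


def _candidate_patch(cand: CandidateRegion, img: np.ndarray, pad: int = 2) -> np.ndarray:
    """Image window around the candidate: bounding box dilated by ``pad``,
    grown (with surrounding image context) to at least 32x32 so every GLCM
    offset is computable; edge-replicated only where the image itself runs
    out."""
    r0, c0, r1, c1 = cand.bbox
    r0, c0, r1, c1 = r0 - pad, c0 - pad, r1 + pad, c1 + pad

    def grow(lo, hi, size):
        need = MIN_PATCH - (hi - lo)
        if need > 0:
            lo -= need // 2
            hi += need - need // 2
        shift = max(0, -lo) - max(0, hi - size)
        lo, hi = lo + shift, hi + shift
        return max(lo, 0), min(hi, size)

    rr0, rr1 = grow(r0, r1, img.shape[0])
    cc0, cc1 = grow(c0, c1, img.shape[1])
    patch = np.asarray(img[rr0:rr1, cc0:cc1], dtype=np.float64)
    h, w = patch.shape
    if h < MIN_PATCH or w < MIN_PATCH:
        patch = np.pad(
            patch,
            ((0, max(0, MIN_PATCH - h)), (0, max(0, MIN_PATCH - w))),
            mode="edge",
        )
    return patch


def extract_features(
    cand: CandidateRegion,
    img: np.ndarray,
    levels: int = GLCM_LEVELS,
) -> FeatureVector:
    """Compute the full 96-feature vector for one candidate region.

    Shape features come from the candidate's binary mask; first-order
    statistics from the image values under the mask; GLCM features from the
    patch around the bounding box (dilated by 2 px, zero-padded to at least
    32x32 so all offsets are computable).
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(cand.mask, dtype=bool)
    if mask.sum() < 2:
        raise FeatureError(
            f"degenerate candidate at {cand.centroid}: area {int(mask.sum())} < 2"
        )

    props = measure.regionprops(mask.astype(np.uint8))[0]
    perimeter = float(props.perimeter)
    area = float(props.area)
    minor = float(props.axis_minor_length)
    major = float(props.axis_major_length)
    values: dict[str, float] = {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_eccentricity": float(props.eccentricity),
        "shape_solidity": float(props.solidity),
        "shape_extent": float(props.extent),
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_aspect_ratio": major / minor if minor > 0 else 1.0,
        "shape_equivalent_diameter": float(props.equivalent_diameter_area),
        "shape_circularity": 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0,
        "shape_convex_area": float(props.area_convex),
        "shape_orientation": float(props.orientation),
    }

    r0, c0, r1, c1 = cand.bbox
    vals = img[r0:r1, c0:c1][mask]
    values.update(
        {
            "intensity_mean": float(vals.mean()),
            "intensity_std": float(vals.std()),
            "intensity_min": float(vals.min()),
            "intensity_max": float(vals.max()),
            "intensity_median": float(np.median(vals)),
            "intensity_skewness": float(sstats.skew(vals)) if vals.std() > 1e-8 else 0.0,
            "intensity_kurtosis": float(sstats.kurtosis(vals)) if vals.std() > 1e-8 else 0.0,
            "intensity_energy": float((vals**2).sum()),
            "intensity_entropy": _histogram_entropy(vals),
            "intensity_range": float(vals.max() - vals.min()),
            "intensity_p10": float(np.percentile(vals, 10)),
            "intensity_p90": float(np.percentile(vals, 90)),
        }
    )

    patch_q = quantise(_candidate_patch(cand, img), levels)
    for off in GLCM_OFFSETS:
        per_angle = {p: [] for p in GLCM_PROPERTIES}
        for ang in GLCM_ANGLES:
            P = glcm(patch_q, levels=levels, angle=ang, offset=off)
            for prop, v in glcm_properties(P).items():
                per_angle[prop].append(v)
        for prop in GLCM_PROPERTIES:
            arr = np.asarray(per_angle[prop])
            values[f"glcm_{prop}_d{off}_mean"] = float(arr.mean())
            values[f"glcm_{prop}_d{off}_std"] = float(arr.std())

    assert set(values) == set(FEATURE_NAMES)
    if not np.isfinite(list(values.values())).all():
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise FeatureError(f"non-finite features {bad} at {cand.centroid}")
    return FeatureVector(values=values, patient_id=cand.patient_id, candidate=cand)


def _histogram_entropy(vals: np.ndarray, bins: int = 32) -> float:
    hist, _ = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def features_to_frame(fvs: list[FeatureVector], labels=None) -> pd.DataFrame:
    """Stack feature vectors into a table with schema-ordered columns."""
    rows = []
    for i, fv in enumerate(fvs):
        row = {"patient_id": fv.patient_id}
        row.update({n: fv.values[n] for n in FEATURE_NAMES})
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectionReport:
    """Per-feature selection outcome: t-test p-value, importance, kept?"""

    p_values: pd.Series
    importances: pd.Series
    selected: list[str]


def select_features(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    p_cut: float = 0.05,
    top_k: int = 20,
    seed: int = 0,
) -> SelectionReport:
    """Two-stage feature selection: Welch t-test screen, then ranking of the
    survivors by permutation importance from a random-forest surrogate.

    If no feature passes the screen, the ``top_k`` smallest p-values are
    kept so the selected set is never empty.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=np.float64)
    else:
        Xa = np.asarray(X, dtype=np.float64)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    a, b = Xa[labels == classes[0]], Xa[labels == classes[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 samples per class")

    with np.errstate(invalid="ignore"):
        _, p = sstats.ttest_ind(a, b, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    p_series = pd.Series(p, index=names)

    survivors = [n for n, pv in p_series.items() if pv < p_cut]
    if not survivors:
        survivors = list(p_series.nsmallest(top_k).index)

    cols = [names.index(n) for n in survivors]
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(Xa[:, cols], labels)
    imp = permutation_importance(
        rf, Xa[:, cols], labels, n_repeats=5, random_state=seed
    ).importances_mean
    imp_series = pd.Series(0.0, index=names)
    imp_series[survivors] = imp

    ranked = sorted(survivors, key=lambda n: (-imp_series[n], p_series[n]))
    selected = ranked[:top_k]
    return SelectionReport(p_values=p_series, importances=imp_series, selected=selected)
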