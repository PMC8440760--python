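import numpy as np
import pandas as pd
import pytest
from skimage.morphology import disk

from mammosub.detection import CandidateRegion
from mammosub.features import (
    FEATURE_NAMES,
    GLCM_ANGLES,
    GLCM_OFFSETS,
    FeatureError,
    N_FEATURES,
    N_GLCM_FEATURES,
    extract_features,
    glcm,
    glcm_properties,
    quantise,
    select_features,
)

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(patch, levels, angle, offset):
    """Pair enumeration with explicit python loops."""
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    h, w = patch.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[patch[r, c], patch[r2, c2]] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_textbook_4x4_pair_counts(self):
        patch = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        P = glcm(patch, levels=4, angle=0, offset=1)
        # 12 horizontal pairs in a 4x4 patch; (0,0) occurs twice
        assert P[0, 0] * 12 == pytest.approx(2.0)

    def test_constant_patch_single_unit_entry(self):
        P = glcm(np.full((6, 6), 3), levels=8, angle=90, offset=2)
        assert P[3, 3] == 1.0 and P.sum() == 1.0

    @pytest.mark.parametrize("angle", GLCM_ANGLES)
    @pytest.mark.parametrize("offset", [1, 2, 3])
    def test_matches_brute_force_on_8x8(self, angle, offset, rng):
        for _ in range(5):
            patch = rng.integers(0, 8, (8, 8))
            np.testing.assert_array_equal(
                glcm(patch, levels=8, angle=angle, offset=offset),
                brute_force_glcm(patch, 8, angle, offset),
            )

    @pytest.mark.parametrize("angle", GLCM_ANGLES)
    @pytest.mark.parametrize("offset", GLCM_OFFSETS)
    def test_matches_brute_force_on_32x32_paper_grid(self, angle, offset, rng):
        patch = rng.integers(0, 32, (32, 32))
        np.testing.assert_array_equal(
            glcm(patch, levels=32, angle=angle, offset=offset),
            brute_force_glcm(patch, 32, angle, offset),
        )

    def test_normalised_but_not_symmetric(self, rng):
        patch = rng.integers(0, 4, (10, 10))
        P = glcm(patch, levels=4, angle=0, offset=1)
        assert P.sum() == pytest.approx(1.0)
        assert not np.allclose(P, P.T)

    def test_oversized_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            glcm(np.zeros((8, 8), dtype=int), levels=4, angle=0, offset=15)

    def test_property_values_on_identity_matrix(self):
        P = np.eye(4) / 4.0
        props = glcm_properties(P)
        assert props["contrast"] == 0.0
        assert props["dissimilarity"] == 0.0
        assert props["homogeneity"] == pytest.approx(1.0)
        assert props["energy"] == pytest.approx(0.25)
        assert props["max_probability"] == pytest.approx(0.25)
        assert props["entropy"] == pytest.approx(2.0)
        assert props["correlation"] == pytest.approx(1.0)
        assert props["difference_entropy"] == 0.0


def make_disc_candidate(radius=5, bg=0.3, fg=0.8, size=64):
    img = np.full((size, size), bg)
    d = disk(radius).astype(bool)
    o = size // 2 - radius
    img[o : o + d.shape[0], o : o + d.shape[1]][d] = fg
    cand = CandidateRegion(
        mask=d,
        bbox=(o, o, o + d.shape[0], o + d.shape[1]),
        centroid=(size / 2, size / 2),
        area_px=int(d.sum()),
    )
    return cand, img


class TestExtractFeatures:
    def test_schema_has_96_features_72_glcm(self):
        cand, img = make_disc_candidate()
        fv = extract_features(cand, img)
        assert len(fv.values) == N_FEATURES == 96
        assert sum(1 for n in fv.values if n.startswith("glcm_")) == N_GLCM_FEATURES == 72
        assert list(fv.values) == FEATURE_NAMES
        assert np.isfinite(fv.as_array()).all()

    def test_disc_shape_limits(self):
        cand, img = make_disc_candidate(radius=5)
        v = extract_features(cand, img).values
        assert 0.9 <= v["shape_circularity"] <= 1.1
        assert v["shape_eccentricity"] < 0.2

    def test_zero_texture_limit_kills_angular_spread(self):
        # constant patch: all angle matrices identical, so every std-type
        # GLCM feature vanishes exactly
        cand, img = make_disc_candidate(radius=5, bg=0.3, fg=0.3)
        v = extract_features(cand, img).values
        for prop in ("contrast", "entropy", "energy"):
            for off in GLCM_OFFSETS:
                assert v[f"glcm_{prop}_d{off}_std"] == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance_for_integer_shifts(self):
        cand, img = make_disc_candidate()
        v0 = extract_features(cand, img).values
        shift = (7, -5)
        img2 = np.roll(np.roll(img, shift[0], axis=0), shift[1], axis=1)
        r0, c0, r1, c1 = cand.bbox
        cand2 = CandidateRegion(
            mask=cand.mask,
            bbox=(r0 + shift[0], c0 + shift[1], r1 + shift[0], c1 + shift[1]),
            centroid=(cand.centroid[0] + shift[0], cand.centroid[1] + shift[1]),
            area_px=cand.area_px,
        )
        v1 = extract_features(cand2, img2).values
        for n in FEATURE_NAMES:
            assert abs(v0[n] - v1[n]) < 1e-9, n

    def test_degenerate_mask_rejected(self):
        cand = CandidateRegion(
            mask=np.array([[True]]), bbox=(0, 0, 1, 1), centroid=(0.0, 0.0), area_px=1
        )
        with pytest.raises(FeatureError, match="degenerate"):
            extract_features(cand, np.zeros((8, 8)))


class TestSelectFeatures:
    def _table(self, rng, n=50):
        X = rng.standard_normal((2 * n, 30))
        y = np.array([0] * n + [1] * n)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(30)]), y

    def test_identical_feature_not_selected(self, rng):
        X, y = self._table(rng)
        X["f0"] = 1.7  # constant in both classes
        rep = select_features(X, y, p_cut=0.05, top_k=5)
        assert rep.p_values["f0"] > 0.9
        assert "f0" not in rep.selected

    def test_strongly_separated_feature_selected(self, rng):
        X, y = self._table(rng)
        X.loc[y == 1, "f3"] += 10.0  # 10 SD mean shift
        rep = select_features(X, y, p_cut=0.05, top_k=5)
        assert rep.p_values["f3"] < 1e-10
        assert "f3" in rep.selected

    def test_selected_set_bounded_and_nonempty(self, rng):
        X, y = self._table(rng, n=20)
        rep = select_features(X, y, top_k=7)
        assert 1 <= len(rep.selected) <= 7

    def test_single_class_rejected(self, rng):
        X, _ = self._table(rng, n=10)
        with pytest.raises(ValueError):
            select_features(X, np.zeros(20, dtype=int))


def test_quantise_maps_unit_interval_to_levels(rng):
    patch = rng.random((8, 8))
    q = quantise(patch, levels=32)
    assert q.min() >= 0 and q.max() <= 31
    assert quantise(np.ones((2, 2)), 32).max() == 31
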