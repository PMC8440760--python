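import numpy as np
import pytest

from mammosub.detection import (
    CandidateRegion,
    binarise,
    detect,
    match_candidates,
    match_candidates_bruteforce,
    morph_clean,
    optimise_threshold,
    range_filter,
)


class _Pt:
    def __init__(self, y, x):
        self.y, self.x = y, x


def brute_force_range(img, window):
    """Nested-loop local max - min with replicated borders."""
    h, w = img.shape
    half = window // 2
    out = np.zeros_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(r - half, 0), min(r + half + 1, h)
            c0, c1 = max(c - half, 0), min(c + half + 1, w)
            block = img[r0:r1, c0:c1]
            out[r, c] = block.max() - block.min()
    return out


class TestRangeFilter:
    def test_constant_image_gives_zeros(self):
        assert np.all(range_filter(np.full((10, 10), 0.4)) == 0.0)

    def test_single_bright_pixel_lights_3x3_block(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = range_filter(img, window=3)
        expected = np.zeros((9, 9))
        expected[3:6, 3:6] = 1.0
        np.testing.assert_array_equal(out, expected)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_brute_force_oracle(self, window, rng):
        for _ in range(5):
            img = rng.random((16, 16))
            np.testing.assert_allclose(
                range_filter(img, window), brute_force_range(img, window)
            )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            range_filter(np.zeros((4, 4)), window=4)


class TestBinarise:
    def test_threshold_splits_values(self):
        out = binarise(np.array([[0.4, 0.6]]), 0.5)
        np.testing.assert_array_equal(out, [[False, True]])

    def test_near_zero_threshold_is_positive_support(self, rng):
        img = rng.random((8, 8)) * (rng.random((8, 8)) > 0.5)
        np.testing.assert_array_equal(binarise(img, 1e-9), img > 0)

    def test_count_non_increasing_in_threshold(self, rng):
        img = rng.random((12, 12))
        counts = [binarise(img, t).sum() for t in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_threshold_rejected(self, t):
        with pytest.raises(ValueError):
            binarise(np.zeros((2, 2)), t)


class TestMorphClean:
    def test_area_filter_drops_specks(self):
        img = np.zeros((20, 20), dtype=bool)
        img[2, 2] = True
        img[17, 3] = True
        img[5:11, 5:10] = True  # 30-px blob
        cands = morph_clean(img, min_area=5, gap_close_radius=0)
        assert len(cands) == 1
        assert cands[0].area_px == 30

    def test_closing_bridges_hairline_gap(self):
        img = np.zeros((10, 20), dtype=bool)
        img[3:7, 2:9] = True
        img[3:7, 10:17] = True  # 1-px gap at column 9
        assert len(morph_clean(img, min_area=4, gap_close_radius=2)) == 1
        assert len(morph_clean(img, min_area=4, gap_close_radius=0)) == 2

    def test_candidates_are_connected_and_large_enough(self, rng):
        from scipy import ndimage

        img = rng.random((40, 40)) > 0.75
        for cand in morph_clean(img, min_area=4, gap_close_radius=1):
            assert cand.area_px >= 4
            _, n = ndimage.label(cand.mask, structure=np.ones((3, 3)))
            assert n == 1
            r0, c0, r1, c1 = cand.bbox
            assert r0 <= cand.centroid[0] < r1 and c0 <= cand.centroid[1] < c1


class TestMatching:
    def _cand(self, y, x, size=3):
        mask = np.ones((size, size), dtype=bool)
        h = size // 2
        return CandidateRegion(
            mask=mask,
            bbox=(y - h, x - h, y + h + 1, x + h + 1),
            centroid=(float(y), float(x)),
            area_px=size * size,
        )

    def test_exact_hit(self):
        m = match_candidates([self._cand(10, 10)], [_Pt(10, 10)], tol_px=8)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_one_to_one_rule(self):
        cands = [self._cand(10, 10), self._cand(12, 10)]
        m = match_candidates(cands, [_Pt(11, 10)], tol_px=8)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_nearest_candidate_wins(self):
        cands = [self._cand(30, 30), self._cand(11, 10)]
        m = match_candidates(cands, [_Pt(10, 10)], tol_px=8)
        assert m.pairs == [(1, 0)]

    def test_far_annotation_is_missed(self):
        m = match_candidates([self._cand(0, 0)], [_Pt(30, 30)], tol_px=8)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    @pytest.mark.parametrize("n_c,n_a", [(3, 3), (4, 2), (2, 5), (5, 5)])
    def test_matching_equals_exhaustive_assignment_cardinality(self, n_c, n_a, rng):
        for _ in range(10):
            cands = [
                self._cand(int(r), int(c))
                for r, c in rng.integers(5, 40, (n_c, 2))
            ]
            anns = [_Pt(int(r), int(c)) for r, c in rng.integers(5, 40, (n_a, 2))]
            matched = match_candidates(cands, anns, tol_px=8).tp
            optimal = match_candidates_bruteforce(cands, anns, tol_px=8)
            assert matched == optimal


class TestOptimiseThreshold:
    def _make_set(self, rng):
        img = np.zeros((40, 40))
        pts = [(10, 10), (25, 30)]
        for r, c in pts:
            img[r - 1 : r + 2, c - 1 : c + 2] = 0.8
        img += 0.05 * rng.random((40, 40))
        return [(img, None, [_Pt(r, c) for r, c in pts])]

    def test_returns_grid_argmax(self, rng):
        data = self._make_set(rng)
        grid = [0.1, 0.3, 0.5, 0.9]
        t = optimise_threshold(data, grid)

        def objective(th):
            tot = 0
            for img, mask, anns in data:
                m = match_candidates(detect(img, mask, threshold=th), anns, tol_px=8)
                tot += m.tp - m.fp
            return tot

        assert objective(t) == max(objective(g) for g in grid)

    def test_singleton_grid_returned(self, rng):
        assert optimise_threshold(self._make_set(rng), [0.42]) == 0.42

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            optimise_threshold(self._make_set(rng), [])


def test_new_spot_centroids_covered_on_phantom_diffs():
    """Detection on subtracted phantoms captures the seeded new spots
    (single-seed smoke version of the 10-seed acceptance check)."""
    from mammosub.pipeline import run_pair
    from mammosub.phantom import PhantomSpec, make_phantom_pair

    pair = make_phantom_pair(PhantomSpec(seed=2))
    res = run_pair(pair.recent, pair.prior)
    new_anns = [t.annotation for t in pair.truth if t.status == "new"]
    m = match_candidates(res.candidates, new_anns, tol_px=8)
    assert m.tp >= int(0.8 * len(new_anns))
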