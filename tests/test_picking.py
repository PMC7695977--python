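"""Template picking: correlation maps, segmentation, filtering, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamspa import picking, synthetic


CFG = picking.PickConfig(particle_radius=14.0, box_size=48,
                         rotation_step=None)


def brute_force_ncc(image, template, mask_radius, x, y):
    """Direct sliding-window locally normalized correlation at one point."""
    box = template.shape[0]
    half = box // 2
    yy, xx = np.mgrid[0:box, 0:box].astype(float)
    c = (box - 1) / 2.0
    mask = np.hypot(xx - c, yy - c) <= mask_radius
    t = template[mask]
    t = t - t.mean()
    win = image[y - half:y - half + box, x - half:x - half + box][mask]
    w = win - win.mean()
    denom = np.linalg.norm(t) * np.linalg.norm(w)
    return float((t * w).sum() / denom) if denom > 0 else 0.0


class TestLocalCorrelation:
    def test_planted_reference_peaks_at_plant(self):
        rng = np.random.default_rng(0)
        ref = synthetic.particle_reference(box=32, seed=2)
        img = rng.normal(0, 0.1, (256, 256))
        img, _ = synthetic.plant_particles(img, ref, [(130.0, 90.0)])
        cmap = picking.local_correlation(img, ref, mask_radius=14)
        # ignore a border margin where the window wraps
        inner = cmap[20:-20, 20:-20]
        iy, ix = np.unravel_index(np.argmax(inner), inner.shape)
        assert (ix + 20, iy + 20) == (130, 90)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        ref = synthetic.particle_reference(box=32, seed=3)
        img = rng.normal(size=(256, 256))
        img, _ = synthetic.plant_particles(img, ref, [(128.0, 128.0)])
        cmap = picking.local_correlation(img, ref, mask_radius=14)
        for (x, y) in ((128, 128), (60, 200), (200, 60), (100, 150)):
            assert cmap[y, x] == pytest.approx(
                brute_force_ncc(img, ref, 14, x, y), abs=1e-6)

    def test_perfect_match_value_one(self):
        ref = synthetic.particle_reference(box=32, seed=4)
        img, _ = synthetic.plant_particles(np.zeros((256, 256)), ref,
                                           [(128.0, 128.0)])
        cmap = picking.local_correlation(img, ref, mask_radius=14)
        assert cmap[128, 128] == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_affine_intensity_changes(self):
        rng = np.random.default_rng(2)
        ref = synthetic.particle_reference(box=32, seed=5)
        img = rng.normal(size=(256, 256))
        a = picking.local_correlation(img, ref, mask_radius=14)
        b = picking.local_correlation(3.7 * img + 11.0, ref, mask_radius=14)
        assert np.abs(a - b)[20:-20, 20:-20].max() < 1e-6

    def test_values_bounded(self, picking_fixture):
        mic, _, ref = picking_fixture
        cmap = picking.local_correlation(mic, ref, mask_radius=14)
        assert cmap.max() <= 1 + 1e-6
        assert cmap.min() >= -1 - 1e-6

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            picking.local_correlation(np.zeros((128, 128)),
                                      np.ones((32, 32)), 14)


class TestCombineMaps:
    def test_single_map_identity(self):
        m = np.random.default_rng(0).normal(size=(64, 64))
        assert np.array_equal(picking.combine_maps([m]), m)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 16, 16))
        got = picking.combine_maps([a, b])
        for i in range(16):
            for j in range(16):
                assert got[i, j] == max(a[i, j], b[i, j])

    def test_dominates_every_input(self):
        rng = np.random.default_rng(2)
        maps = list(rng.normal(size=(4, 32, 32)))
        combined = picking.combine_maps(maps)
        for m in maps:
            assert (combined >= m).all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            picking.combine_maps([])


def brute_force_otsu2d(cmap, bins=64):
    """Exhaustive 2D-threshold search maximizing between-class variance."""
    from scipy import ndimage as ndi
    lo, hi = cmap.min(), cmap.max()
    smooth = ndi.uniform_filter(cmap, size=3, mode="nearest")
    v = np.clip(((cmap - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    s = np.clip(((smooth - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    best, best_ij = -np.inf, (0, 0)
    vi = v.ravel().astype(float)
    si = s.ravel().astype(float)
    for i in range(bins):
        for j in range(bins):
            in0 = (vi <= i) & (si <= j)
            in1 = (vi > i) & (si > j)
            w0, w1 = in0.mean(), in1.mean()
            if w0 <= 0 or w1 <= 0:
                continue
            mu0 = (vi[in0].mean(), si[in0].mean())
            mu1 = (vi[in1].mean(), si[in1].mean())
            mt = (vi.mean(), si.mean())
            sb = w0 * ((mu0[0] - mt[0]) ** 2 + (mu0[1] - mt[1]) ** 2) \
                + w1 * ((mu1[0] - mt[0]) ** 2 + (mu1[1] - mt[1]) ** 2)
            if sb > best:
                best, best_ij = sb, (i, j)
    return (v > best_ij[0]) & (s > best_ij[1])


class TestOtsu2d:
    def test_bimodal_map_recovers_high_mode(self):
        rng = np.random.default_rng(3)
        cmap = rng.normal(0.0, 0.05, (128, 128))
        truth = np.zeros((128, 128), dtype=bool)
        truth[30:50, 30:50] = True
        truth[80:100, 60:80] = True
        cmap[truth] += 1.0
        mask = picking.segment_otsu2d(cmap)
        agreement = (mask == truth).mean()
        assert agreement >= 0.99

    def test_constant_map_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = picking.segment_otsu2d(np.full((64, 64), 2.0))
        assert not mask.any()

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(4)
        cmap = rng.normal(0, 0.1, (64, 64))
        cmap[20:30, 20:30] += 0.8
        fast = picking.segment_otsu2d(cmap, bins=64)
        brute = brute_force_otsu2d(cmap, bins=64)
        assert np.array_equal(fast, brute)


class TestDistanceFilter:
    def _map_with_peaks(self, peaks, shape=(256, 256)):
        cmap = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        for x, y, score in peaks:
            cmap[y, x] = score
            mask[y - 1:y + 2, x - 1:x + 2] = True
        return cmap, mask

    def test_distant_pair_both_kept(self):
        thr = CFG.min_distance
        sep = int(1.5 * thr)
        cmap, mask = self._map_with_peaks([(50, 50, 0.9),
                                           (50 + sep, 50, 0.8)])
        kept = [p for p in picking.detect_and_filter_peaks(cmap, mask, CFG)
                if p.accepted]
        assert len(kept) == 2

    def test_close_pair_keeps_highest(self):
        thr = CFG.min_distance
        sep = int(0.5 * thr)
        cmap, mask = self._map_with_peaks([(50, 50, 0.9),
                                           (50 + sep, 50, 0.7)])
        peaks = picking.detect_and_filter_peaks(cmap, mask, CFG)
        kept = [p for p in peaks if p.accepted]
        assert len(kept) == 1
        assert kept[0].score == pytest.approx(0.9)
        dropped = [p for p in peaks if not p.accepted]
        assert dropped[0].reject_reason == "distance"

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_no_kept_pair_within_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 25)
        peaks = [(int(x), int(y), float(s))
                 for x, y, s in zip(rng.integers(10, 246, n),
                                    rng.integers(10, 246, n),
                                    rng.uniform(0.1, 1.0, n))]
        cmap, mask = self._map_with_peaks(peaks)
        kept = [p for p in picking.detect_and_filter_peaks(cmap, mask, CFG)
                if p.accepted]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert np.hypot(a.x - b.x, a.y - b.y) >= CFG.min_distance


class TestOutliers:
    def test_contamination_square_rejected(self):
        rng = np.random.default_rng(0)
        ref = synthetic.particle_reference(48, 7)
        coords = [(float(x), float(y)) for x in range(100, 700, 120)
                  for y in range(100, 700, 120)]
        sq_pos = coords.pop(17)
        clean = np.zeros((768, 768))
        clean, _ = synthetic.plant_particles(clean, ref, coords)
        square = np.zeros((48, 48))
        square[10:38, 10:38] = 1.0
        img, _ = synthetic.plant_particles(clean, square, [sq_pos],
                                           amplitude=6.0 * ref.max())
        mic = img + rng.normal(0, np.sqrt(clean.var() / 0.5), (768, 768))
        peaks, _ = picking.pick_particles(mic, ref, CFG)
        near_square = [p for p in peaks
                       if np.hypot(p.x - sq_pos[0], p.y - sq_pos[1]) < 24]
        assert near_square
        assert all(not p.accepted and p.reject_reason == "outlier"
                   for p in near_square)

    def test_homogeneous_peaks_none_rejected(self, picking_fixture):
        mic, coords, _ = picking_fixture
        peaks = [picking.PickedParticle(x, y, 0.9) for x, y in coords]
        out = picking.reject_outliers(mic, peaks, CFG)
        assert all(p.accepted for p in out)

    def test_edge_peak_dropped(self, picking_fixture):
        mic, _, _ = picking_fixture
        peaks = [picking.PickedParticle(5.0, 5.0, 0.9)] \
            + [picking.PickedParticle(100.0 + 60 * i, 200.0, 0.8)
               for i in range(5)]
        out = picking.reject_outliers(mic, peaks, CFG)
        edge = [p for p in out if p.x == 5.0][0]
        assert not edge.accepted
        assert edge.reject_reason == "edge"

    def test_small_population_skips_rejection(self, picking_fixture):
        mic, _, _ = picking_fixture
        peaks = [picking.PickedParticle(100.0, 100.0, 0.9),
                 picking.PickedParticle(300.0, 300.0, 0.8)]
        with pytest.warns(UserWarning, match="fewer than 5"):
            out = picking.reject_outliers(mic, peaks, CFG)
        assert all(p.accepted for p in out)


class TestExtraction:
    def test_background_annulus_normalized(self, picking_fixture):
        mic, coords, _ = picking_fixture
        peaks = [picking.PickedParticle(float(x), float(y), 1.0)
                 for x, y in coords[:5]]
        stack = picking.extract_particles(mic, peaks, CFG)
        b = CFG.box_size
        yy, xx = np.mgrid[0:b, 0:b].astype(float)
        c = (b - 1) / 2.0
        bg = np.hypot(xx - c, yy - c) > CFG.particle_radius
        for win in stack:
            assert win[bg].mean() == pytest.approx(0.0, abs=1e-6)
            assert win[bg].std() == pytest.approx(1.0, abs=1e-6)

    def test_stack_count_equals_accepted(self, picking_fixture):
        mic, _, ref = picking_fixture
        peaks, stack = picking.pick_particles(mic, ref, CFG)
        assert len(stack) == sum(1 for p in peaks if p.accepted)

    def test_planted_particle_recovered_up_to_affine(self):
        ref = synthetic.particle_reference(48, 7)
        img, coords = synthetic.plant_particles(np.zeros((256, 256)), ref,
                                                [(128.0, 128.0)])
        img = img + 0.01  # constant offset removed by normalization
        peaks = [picking.PickedParticle(128.0, 128.0, 1.0)]
        stack = picking.extract_particles(img, peaks, CFG)
        win = stack[0]
        # affine match: corrcoef 1 against the reference
        assert np.corrcoef(win.ravel(), ref.ravel())[0, 1] > 0.999


class TestEndToEnd:
    def test_recall_and_precision(self, picking_fixture):
        mic, coords, ref = picking_fixture
        peaks, _ = picking.pick_particles(mic, ref, CFG)
        acc = [p for p in peaks if p.accepted]
        hits = sum(1 for cx, cy in coords
                   if any(np.hypot(p.x - cx, p.y - cy) <= 3 for p in acc))
        false = sum(1 for p in acc
                    if not any(np.hypot(p.x - cx, p.y - cy)
                               <= CFG.min_distance for cx, cy in coords))
        assert hits / len(coords) >= 0.9
        assert false / max(len(acc), 1) <= 0.1
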