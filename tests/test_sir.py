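"""SIR: boundary tracing, RP handling, patch decisions, aggregation."""

import numpy as np
import pytest
from scipy import ndimage

from slipscan import (
    SIRParams,
    RPImage,
    PointLabel,
    adhesion_percentages,
    classify_point,
    classify_slice,
    extract_rp,
    run_sir,
    select_patch,
    standardize_rp,
    trace_boundary,
)


# ---------------------------------------------------------------- oracle

def sir_oracle(noss_slice, roi_slice, params):
    """Exhaustive, loop-based re-evaluation of the three conditions at
    every boundary pixel; independent of the library code path."""
    roi = roi_slice.astype(bool)
    h, w = roi.shape
    rs, cs = np.where(roi)
    pad = params.rp_pad_vox
    r0, r1 = max(rs.min() - pad, 0), min(rs.max() + pad, h - 1)
    c0, c1 = max(cs.min() - pad, 0), min(cs.max() + pad, w - 1)
    rp = np.array(noss_slice, float)[r0 : r1 + 1, c0 : c1 + 1]
    finite = np.isfinite(rp)
    vmax = rp[finite].max() if finite.any() else 0.0
    if vmax > 0:
        rp = rp / vmax
    rp_max = rp[np.isfinite(rp)].max()
    rp_min = rp[np.isfinite(rp)].min()

    lab, n = ndimage.label(roi, structure=np.ones((3, 3)))
    keep = {i for i in range(1, n + 1) if (lab == i).sum() >= params.min_roi_pixels_per_slice}

    def patch_stats(pr, pc, size):
        half = size // 2
        vals = []
        for dr in range(-half, half + 1):
            for dc in range(-half, half + 1):
                rr = min(max(pr + dr, 0), rp.shape[0] - 1)
                cc = min(max(pc + dc, 0), rp.shape[1] - 1)
                if np.isfinite(rp[rr, cc]):
                    vals.append(rp[rr, cc])
        if not vals:
            return None
        return min(vals), max(vals), sum(vals) / len(vals)

    out = {}
    for r in range(h):
        for c in range(w):
            if not roi[r, c] or lab[r, c] not in keep:
                continue
            nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if all(0 <= a < h and 0 <= b < w and roi[a, b] for a, b in nbrs):
                continue  # not a boundary pixel
            pr, pc = r - r0, c - c0
            i_a = rp[pr, pc]
            if not np.isfinite(i_a):
                continue
            st3 = patch_stats(pr, pc, 3)
            if st3 is None or abs(st3[2] - i_a) < params.patch_escalation_threshold:
                st = patch_stats(pr, pc, 5)
            else:
                st = st3
            if st is None:
                continue
            pmin, pmax, pmean = st
            if i_a > params.cond1_max_frac * rp_max or i_a < params.cond1_min_frac * rp_min:
                out[(r, c)] = (True, "I")
                continue
            tau = params.cond2_tau_frac * (pmax - pmin)
            if abs(i_a - pmean) > tau:
                out[(r, c)] = (True, "II")
            elif (pmax - pmin) > params.cond3_range_frac * i_a:
                out[(r, c)] = (True, "III")
            else:
                out[(r, c)] = (False, "none")
    return out


def random_slice(rng, size=28, masked=False):
    """Smooth positive NOSS-like slice with a filled random blob ROI."""
    noss = ndimage.gaussian_filter(rng.random((size, size)), 2.0) + 0.05
    blob = ndimage.gaussian_filter(rng.random((size, size)), 3.0)
    roi = blob > np.quantile(blob, 0.8)
    roi = ndimage.binary_fill_holes(roi)
    # keep away from the slice edge so the blob is a plausible tumor section
    roi[:2], roi[-2:], roi[:, :2], roi[:, -2:] = False, False, False, False
    if masked:
        noss[rng.random((size, size)) < 0.05] = np.nan
    return noss, roi


# ---------------------------------------------------------------- tracing

class TestTraceBoundary:
    def test_tiny_component_filtered_out(self):
        roi = np.zeros((8, 8), bool)
        roi[3, 3] = True
        assert trace_boundary(roi, min_area=5) == []

    def test_full_3x3_square_perimeter(self):
        roi = np.zeros((7, 7), bool)
        roi[2:5, 2:5] = True
        paths = trace_boundary(roi, min_area=5)
        assert len(paths) == 1
        pts = paths[0].points
        assert len(pts) == 8 and (3, 3) not in pts
        assert pts[0] == (2, 2)  # starts at the top-left boundary pixel

    def test_5x5_square_has_16_boundary_pixels(self):
        roi = np.zeros((9, 9), bool)
        roi[2:7, 2:7] = True
        pts = trace_boundary(roi)[0].points
        expected = {
            (r, c)
            for r in range(2, 7)
            for c in range(2, 7)
            if r in (2, 6) or c in (2, 6)
        }
        assert set(pts) == expected and len(pts) == 16

    def test_disk_path_is_closed_and_8_connected(self, rng):
        for _ in range(5):
            roi = np.zeros((30, 30), bool)
            r0, c0 = rng.integers(12, 18, size=2)
            rad = rng.integers(4, 9)
            rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
            roi[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = True
            (path,) = trace_boundary(roi)
            loop = path.points + [path.points[0]]
            for a, b in zip(loop, loop[1:]):
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_blob_path_visits_each_pixel_once(self, rng):
        for _ in range(5):
            _, roi = random_slice(rng)
            for path in trace_boundary(roi):
                assert len(path.points) == len(set(path.points))

    def test_every_point_has_outside_face_neighbor(self, rng):
        _, roi = random_slice(rng)
        for path in trace_boundary(roi):
            for r, c in path.points:
                nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                assert any(
                    not (0 <= a < roi.shape[0] and 0 <= b < roi.shape[1]) or not roi[a, b]
                    for a, b in nbrs
                )


# ---------------------------------------------------------------- RP

class TestExtractRP:
    def make_roi(self, shape=(40, 40), rows=(10, 19), cols=(5, 16)):
        roi = np.zeros(shape, bool)
        roi[rows[0] : rows[1] + 1, cols[0] : cols[1] + 1] = True
        return roi

    @pytest.mark.parametrize("pad,shape", [(3, (16, 18)), (5, (20, 22))])
    def test_bbox_plus_pad(self, pad, shape):
        roi = self.make_roi()
        rp = extract_rp(np.ones((40, 40)), roi, pad=pad)
        assert rp.intensities.shape == shape
        assert rp.origin == (10 - pad, 5 - pad)

    def test_clipped_at_slice_edge(self):
        roi = self.make_roi(rows=(0, 5), cols=(0, 5))
        rp = extract_rp(np.ones((40, 40)), roi, pad=3)
        assert rp.origin == (0, 0)
        assert rp.intensities.shape == (9, 9)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty ROI"):
            extract_rp(np.ones((4, 4)), np.zeros((4, 4), bool), 3)


class TestStandardizeRP:
    def test_max_becomes_one(self):
        rp = RPImage(np.array([[0.04, 0.02], [0.01, 0.03]]), (0, 0))
        out = standardize_rp(rp)
        np.testing.assert_allclose(out.intensities, [[1.0, 0.5], [0.25, 0.75]])
        assert out.standardized and not out.degenerate

    def test_all_zero_flagged_unchanged(self):
        out = standardize_rp(RPImage(np.zeros((3, 3)), (0, 0)))
        assert out.degenerate
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_masked_entries_ignored_in_max(self):
        vals = np.array([[0.5, np.nan], [0.25, 0.1]])
        out = standardize_rp(RPImage(vals, (0, 0)))
        assert np.nanmax(out.intensities) == 1.0
        assert np.isnan(out.intensities[0, 1])


# ---------------------------------------------------------------- patches

def rp_from(values):
    return RPImage(np.array(values, float), (0, 0), standardized=True)


class TestSelectPatch:
    params = SIRParams()

    def test_large_contrast_keeps_3x3(self):
        vals = np.full((7, 7), 0.20)
        vals[3, 3] = 0.60
        # 3x3 mean = (0.60 + 8*0.20)/9 = 0.2444; |0.60-0.2444| >= 0.065
        patch = select_patch(rp_from(vals), (3, 3), self.params)
        assert patch.size == 3
        assert patch.p_mean == pytest.approx((0.60 + 8 * 0.20) / 9)

    def test_flat_neighborhood_escalates_to_5x5(self):
        vals = np.full((7, 7), 0.30)
        patch = select_patch(rp_from(vals), (3, 3), self.params)
        assert patch.size == 5

    def test_uniform_rp_always_5x5(self):
        patch = select_patch(rp_from(np.ones((9, 9))), (4, 4), self.params)
        assert patch.size == 5 and patch.values.shape == (5, 5)

    def test_edge_replication_at_rp_border(self):
        vals = np.arange(16, dtype=float).reshape(4, 4) / 16
        patch = select_patch(rp_from(vals), (0, 0), self.params)
        # replicated entries mirror the corner row/col values
        assert patch.values.shape[0] in (3, 5)
        assert patch.values[0, 0] == vals[0, 0]

    def test_masked_entries_excluded_from_stats(self):
        vals = np.full((7, 7), 0.2)
        vals[3, 3] = 0.9
        vals[2, 2] = np.nan
        patch = select_patch(rp_from(vals), (3, 3), self.params)
        assert np.isfinite(patch.p_mean)
        assert patch.p_max == 0.9


class TestClassifyPoint:
    params = SIRParams()

    def make_patch(self, values, size=None):
        values = np.array(values, float)
        size = size or values.shape[0]
        from slipscan.sir import _patch_from_values

        return _patch_from_values((0, 0), size, values)

    def test_bright_point_fires_condition_one(self):
        patch = self.make_patch(np.full((3, 3), 0.5))
        na, fired = classify_point(0.90, patch, 1.0, 0.05, self.params)
        assert na and fired == "I"

    def test_step_contrast_fires_condition_two(self):
        vals = np.full((3, 3), 0.15)
        vals[1, 1] = 0.60
        patch = self.make_patch(vals)
        assert patch.p_mean == pytest.approx(0.20)
        na, fired = classify_point(0.60, patch, 1.0, 0.0, self.params)
        assert na and fired == "II"

    def test_high_variation_faint_point_fires_condition_three(self):
        vals = np.full((5, 5), 0.30).ravel()
        vals[:4], vals[4:8] = 0.05, 0.55
        patch = self.make_patch(vals.reshape(5, 5), 5)
        assert patch.p_mean == pytest.approx(0.30)
        na, fired = classify_point(0.30, patch, 1.0, 0.0, self.params)
        assert na and fired == "III"

    def test_uniform_patch_moderate_point_is_adherent(self):
        patch = self.make_patch(np.full((3, 3), 0.40))
        na, fired = classify_point(0.40, patch, 1.0, 0.05, self.params)
        assert not na and fired == "none"

    def test_dark_point_fires_condition_one_lower_branch(self):
        patch = self.make_patch(np.full((3, 3), 0.3))
        na, fired = classify_point(0.05, patch, 1.0, 0.10, self.params)
        # 0.05 < 1.15 * 0.10
        assert na and fired == "I"


# ---------------------------------------------------------------- aggregation

class TestAdhesionPercentages:
    def make_labels(self, spec):
        """spec: list of (slice, n_points, n_non_adherent)."""
        labels = []
        for s, n, k in spec:
            for i in range(n):
                labels.append(
                    PointLabel((s, i, 0), i < k, "II" if i < k else "none")
                )
        return labels

    def test_all_non_adherent(self):
        res = adhesion_percentages(self.make_labels([(0, 4, 4), (1, 6, 6)]))
        assert res.non_adhesion_pct == 100.0 and res.adhesion_pct == 0.0

    def test_three_of_eight(self):
        res = adhesion_percentages(self.make_labels([(0, 8, 3)]))
        assert res.non_adhesion_pct == pytest.approx(37.5)

    def test_pooled_counts_not_slice_means(self):
        res = adhesion_percentages(self.make_labels([(0, 10, 2), (1, 30, 18)]))
        assert res.non_adhesion_pct == pytest.approx(50.0)  # not (20+60)/2
        assert res.per_slice == [(0, 10, 2), (1, 30, 18)]

    def test_percentages_sum_to_100(self):
        res = adhesion_percentages(self.make_labels([(0, 7, 3)]))
        assert res.adhesion_pct + res.non_adhesion_pct == pytest.approx(100.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no analyzable boundary"):
            adhesion_percentages([])


# ---------------------------------------------------------------- run_sir

class TestRunSIR:
    def make_volume(self, rng, n_slices=3):
        noss = np.zeros((28, 28, n_slices + 2))
        mask = np.zeros_like(noss, dtype=bool)
        for z in range(1, n_slices + 1):
            ns, roi = random_slice(rng)
            noss[:, :, z] = ns
            mask[:, :, z] = roi
        return noss, mask

    def test_deterministic(self, rng):
        noss, mask = self.make_volume(rng)
        r1, l1, v1 = run_sir(noss, mask)
        r2, l2, v2 = run_sir(noss, mask)
        assert r1 == r2 and l1 == l2 and np.array_equal(v1, v2)

    def test_label_volume_on_boundary_only(self, rng):
        from slipscan.sir import face_boundary_pixels

        noss, mask = self.make_volume(rng)
        _, _, vol = run_sir(noss, mask)
        for z in range(mask.shape[2]):
            labeled = vol[:, :, z] > 0
            if labeled.any():
                assert not (labeled & ~face_boundary_pixels(mask[:, :, z])).any()

    def test_zero_thresholds_make_everything_non_adherent(self, rng):
        noss, mask = self.make_volume(rng)
        params = SIRParams(cond1_max_frac=0.0)
        res, _, _ = run_sir(noss, mask, params)
        assert res.non_adhesion_pct == 100.0

    def test_global_rescaling_leaves_result_unchanged(self, rng):
        noss, mask = self.make_volume(rng)
        r1, l1, _ = run_sir(noss, mask)
        r2, l2, _ = run_sir(noss * 37.2, mask)
        assert l1 == l2 and r1.non_adhesion_pct == r2.non_adhesion_pct

    def test_no_qualifying_slice_raises(self):
        noss = np.ones((10, 10, 3))
        mask = np.zeros_like(noss, dtype=bool)
        mask[4, 4, 1] = True  # single pixel, below area filter
        with pytest.raises(ValueError, match="area filter"):
            run_sir(noss, mask)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="match"):
            run_sir(np.ones((4, 4, 4)), np.ones((5, 5, 5), bool))


class TestOracleEquivalence:
    @pytest.mark.parametrize("masked", [False, True], ids=["clean", "with_masked"])
    def test_classification_matches_exhaustive_reevaluation(self, masked):
        """Independent loop-based evaluation of Conditions I-III at every
        boundary pixel agrees exactly with the library on random slices."""
        rng = np.random.default_rng(42 if not masked else 43)
        params = SIRParams()
        n_checked = 0
        for _ in range(20):
            noss, roi = random_slice(rng, size=int(rng.integers(20, 33)), masked=masked)
            if roi.sum() < params.min_roi_pixels_per_slice:
                continue
            got, _ = classify_slice(noss, roi, params)
            got = {pt: (na, fired) for pt, na, fired in got}
            expected = sir_oracle(noss, roi, params)
            assert set(got) <= set(expected)
            for pt, lab in got.items():
                assert lab == expected[pt], f"mismatch at {pt}"
            if not masked:
                assert set(got) == set(expected)
            n_checked += len(got)
        assert n_checked > 200

    def test_condition_one_set_shrinks_with_rising_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            noss, roi = random_slice(rng)
            if roi.sum() < 5:
                continue
            lo, _ = classify_slice(noss, roi, SIRParams(cond1_max_frac=0.70))
            hi, _ = classify_slice(noss, roi, SIRParams(cond1_max_frac=0.90))
            fired_lo = {pt for pt, na, f in lo if f == "I"}
            fired_hi = {pt for pt, na, f in hi if f == "I"}
            assert fired_hi <= fired_lo
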