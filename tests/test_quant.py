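"""Myofibril detection, enclosure scoring, filtering, quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fimid
from fimid.quant import CandidateObject, UnquantifiableFiberError

from conftest import (
    CLEAN,
    SMALL,
    enclosure_oracle,
    random_mask_pair,
    windowed_threshold_oracle,
)


def obj(area=1.0, aspect=1.2, encl=0.95, solidity=0.95, oid=0):
    return CandidateObject(
        object_id=oid,
        area_um2=area,
        major_axis_um=aspect,
        minor_axis_um=1.0,
        solidity=solidity,
        enclosure_fraction=encl,
        centroid=(0.0, 0.0),
    )


class TestBinarizeBoundary:
    def test_constant_image_empty_mask(self):
        assert not fimid.binarize_boundary(np.full((32, 32), 7.0)).any()

    @pytest.mark.parametrize("window", [2, 1, -3])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            fimid.binarize_boundary(np.zeros((8, 8)), window_px=window)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(21)
        img = rng.random((32, 32)) * 100
        for window, sens in [(5, 0.5), (9, 0.3)]:
            got = fimid.binarize_boundary(img, window, sens)
            assert np.array_equal(got, windowed_threshold_oracle(img, window, sens))

    def test_recovers_clean_ridge(self, clean_render):
        stack, gt = clean_render
        mask = fimid.binarize_boundary(stack.plane("serca", 0).astype(float))
        mask &= gt.fiber_mask
        truth = gt.boundary_mask & gt.fiber_mask
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.9


class TestEnclosureFraction:
    def test_fully_ringed_square(self):
        obj_mask = np.zeros((9, 9), dtype=bool)
        obj_mask[3:6, 3:6] = True
        ring = np.zeros((9, 9), dtype=bool)
        ring[2:7, 2:7] = True
        ring[3:6, 3:6] = False
        assert fimid.enclosure_fraction(obj_mask, ring, reach_px=1) == 1.0

    def test_no_boundary(self):
        obj_mask = np.zeros((9, 9), dtype=bool)
        obj_mask[3:6, 3:6] = True
        assert fimid.enclosure_fraction(obj_mask, np.zeros((9, 9), bool), 1) == 0.0

    def test_top_edge_deleted_matches_oracle(self):
        obj_mask = np.zeros((16, 16), dtype=bool)
        obj_mask[4:13, 4:13] = True  # 9x9 square
        ring = np.zeros((16, 16), dtype=bool)
        ring[3:14, 3:14] = True
        ring[4:13, 4:13] = False
        ring[3, :] = False  # delete boundary along the top
        got = fimid.enclosure_fraction(obj_mask, ring, reach_px=1)
        assert got == enclosure_oracle(obj_mask, ring, 1)
        assert got < 1.0

    @pytest.mark.parametrize("case", range(12))
    def test_random_masks_match_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        size = int(rng.integers(8, 33))
        reach = int(rng.integers(1, 4))
        o, b = random_mask_pair(rng, size)
        assert fimid.enclosure_fraction(o, b, reach) == enclosure_oracle(o, b, reach)

    def test_monotone_in_boundary_growth(self):
        rng = np.random.default_rng(7)
        o, b = random_mask_pair(rng, 24)
        grown = (b | (rng.random(b.shape) < 0.2)) & ~o
        assert fimid.enclosure_fraction(o, grown, 2) >= fimid.enclosure_fraction(
            o, b, 2
        )

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            fimid.enclosure_fraction(np.zeros((4, 4), bool), np.zeros((4, 4), bool), 1)
        overlap = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            fimid.enclosure_fraction(overlap, overlap, 1)


class TestDetectCandidates:
    def test_empty_boundary_gives_no_candidates(self):
        fiber = np.zeros((32, 32), dtype=bool)
        fiber[4:28, 4:28] = True
        got = fimid.detect_candidates(np.zeros((32, 32), bool), fiber, 0.1)
        assert got == []

    def test_empty_fiber_mask_rejected(self):
        with pytest.raises(ValueError):
            fimid.detect_candidates(
                np.zeros((8, 8), bool), np.zeros((8, 8), bool), 0.1
            )

    def test_clean_fiber_recovers_true_count(self, clean_render, clean_spec):
        """Noise-free, gap-free rendering: one candidate per true domain."""
        _, gt = clean_render
        cands = fimid.detect_candidates(
            gt.boundary_mask, gt.fiber_mask, clean_spec.pixel_size_um
        )
        assert len(cands) == gt.true_count

    def test_translation_invariance(self, clean_render, clean_spec):
        _, gt = clean_render
        px = clean_spec.pixel_size_um
        pad = 8
        b = np.pad(gt.boundary_mask, pad)
        f = np.pad(gt.fiber_mask, pad)
        a1 = fimid.detect_candidates(b, f, px)
        a2 = fimid.detect_candidates(
            np.roll(b, (5, 5), (0, 1)), np.roll(f, (5, 5), (0, 1)), px
        )
        key = lambda objs: sorted(
            (round(o.area_um2, 9), round(o.aspect_ratio, 6)) for o in objs
        )
        assert key(a1) == key(a2)

    def test_rotation_invariance(self, clean_render, clean_spec):
        _, gt = clean_render
        px = clean_spec.pixel_size_um
        a1 = fimid.detect_candidates(gt.boundary_mask, gt.fiber_mask, px)
        a2 = fimid.detect_candidates(
            np.rot90(gt.boundary_mask), np.rot90(gt.fiber_mask), px
        )
        areas = lambda objs: sorted(round(o.area_um2, 9) for o in objs)
        assert areas(a1) == areas(a2)


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "kwargs,status",
        [
            (dict(aspect=3.0), "rejected:aspect"),
            (dict(encl=0.85), "rejected:enclosure"),
            (dict(), "accepted"),
            (dict(area=0.01), "rejected:size"),
            (dict(solidity=0.5), "rejected:shape"),
        ],
    )
    def test_single_rules(self, kwargs, status):
        out = fimid.filter_candidates([obj(**kwargs)])
        assert out[0].status == status

    def test_first_failing_rule_wins(self):
        # fails size AND aspect AND enclosure: reported reason is size
        out = fimid.filter_candidates([obj(area=100.0, aspect=5.0, encl=0.1)])
        assert out[0].status == "rejected:size"

    @given(st.floats(min_value=1.0, max_value=10.0), st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_aspect_max_never_loses_acceptances(self, amax, delta):
        objs = [obj(aspect=a, oid=i) for i, a in enumerate(np.linspace(1, 6, 12))]
        n1 = sum(
            o.status == "accepted" for o in fimid.filter_candidates(objs, aspect_max=amax)
        )
        n2 = sum(
            o.status == "accepted"
            for o in fimid.filter_candidates(objs, aspect_max=amax + delta)
        )
        assert n2 >= n1


class TestIntermyofibrillarArea:
    def test_definition(self):
        fiber = np.ones((10, 10), dtype=bool)
        merged = np.zeros((10, 10), dtype=bool)
        merged[:3, :4] = True  # 12 positive pixels
        assert fimid.intermyofibrillar_area(merged, fiber, 0.1) == pytest.approx(0.12)
        assert fimid.intermyofibrillar_area(np.zeros_like(fiber), fiber, 0.1) == 0.0

    def test_clean_render_matches_truth(self, clean_render, clean_spec):
        _, gt = clean_render
        got = fimid.intermyofibrillar_area(
            gt.boundary_mask, gt.fiber_mask, clean_spec.pixel_size_um
        )
        assert got == pytest.approx(gt.boundary_area_um2, rel=0.05)


class TestQuantifyFiber:
    def test_count_formula(self):
        accepted = [obj(area=1.5, oid=i) for i in range(3)]
        q = fimid.quantify_fiber(0, 1000.0, accepted, 400.0, n_candidates=5)
        assert q.myofibril_occupied_area_um2 == 600.0
        assert q.myofibril_count == pytest.approx(400.0)
        assert q.filter_rate == pytest.approx(2 / 5)

    def test_fully_intermyofibrillar_fiber(self):
        q = fimid.quantify_fiber(0, 500.0, [obj(area=1.0)], 500.0)
        assert q.myofibril_occupied_area_um2 == 0.0
        assert q.myofibril_count == 0.0

    def test_no_accepted_objects(self):
        rejected = fimid.filter_candidates([obj(encl=0.1)])
        with pytest.raises(UnquantifiableFiberError):
            fimid.quantify_fiber(0, 100.0, rejected, 10.0)

    @given(
        st.floats(min_value=10.0, max_value=1e5),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.2, max_value=5.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exact_area_conservation(self, csa, inter_frac, mean_area):
        q = fimid.quantify_fiber(0, csa, [obj(area=mean_area)], inter_frac * csa)
        assert q.myofibril_occupied_area_um2 + q.intermyofibrillar_area_um2 == csa


class TestFilterRateSummary:
    def test_pooling(self):
        def q(n_cand, n_rej):
            accepted = [obj(oid=i) for i in range(n_cand - n_rej)]
            return fimid.quantify_fiber(0, 100.0, accepted, 10.0, n_candidates=n_cand)

        assert fimid.filter_rate_summary([q(10, 4)]) == pytest.approx(0.40)
        assert fimid.filter_rate_summary([q(10, 4), q(30, 18)]) == pytest.approx(0.55)

    def test_matches_per_object_recount(self, small_render, small_spec):
        _, gt = small_render
        cands = fimid.detect_candidates(
            gt.boundary_mask, gt.fiber_mask, small_spec.pixel_size_um
        )
        cands = fimid.filter_candidates(cands)
        q = fimid.quantify_fiber(
            0, gt.fiber_area_um2, cands, gt.boundary_area_um2, len(cands)
        )
        recount = sum(c.status != "accepted" for c in cands) / len(cands)
        assert fimid.filter_rate_summary([q]) == pytest.approx(recount)
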