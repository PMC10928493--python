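"""Synthetic fiber generator: geometry, rendering, ground truth."""

import numpy as np
import pytest

import fimid
from fimid.synthetic import InfeasibleGeometryError, SyntheticSpec, _grid

from conftest import CLEAN, SMALL, shoelace


class TestGeometry:
    def test_seed_determinism(self, small_spec):
        g1 = fimid.generate_geometry(small_spec)
        g2 = fimid.generate_geometry(small_spec)
        for a, b in zip(g1.cells, g2.cells):
            assert np.array_equal(
                np.asarray(a.exterior.coords), np.asarray(b.exterior.coords)
            )

    def test_exact_cell_count(self):
        spec = SyntheticSpec(seed=1, n_myofibrils=50, fiber_radius_um=6.0)
        geom = fimid.generate_geometry(spec)
        assert len(geom.cells) == 50
        assert len(geom.interiors) == 50

    def test_lloyd_relaxation_regularizes_areas(self):
        def cv(lloyd_iters):
            spec = SyntheticSpec(
                seed=11, n_myofibrils=80, fiber_radius_um=6.0, lloyd_iters=lloyd_iters
            )
            areas = np.array([c.area for c in fimid.generate_geometry(spec).cells])
            return areas.std() / areas.mean()

        assert cv(3) < cv(0)

    def test_infeasible_boundary_width(self):
        spec = SyntheticSpec(
            seed=0, n_myofibrils=100, fiber_radius_um=3.0, boundary_width_um=1.5
        )
        with pytest.raises(InfeasibleGeometryError):
            fimid.generate_geometry(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(gap_fraction=1.0).validate()
        with pytest.raises(ValueError):
            SyntheticSpec(n_myofibrils=0).validate()


class TestRender:
    def test_clean_boundary_matches_distance_oracle(self, clean_spec, clean_render):
        """Pixel centers within half the ridge width of the boundary network
        (and inside the fiber) are lit; checked against an independent
        point-to-segment distance computation."""
        stack, gt = clean_render
        geom = fimid.generate_geometry(clean_spec)
        n_px, half = _grid(clean_spec)
        px = clean_spec.pixel_size_um
        half_w = clean_spec.boundary_width_um / 2.0

        segs = []
        for ln in geom.boundary_lines:
            xy = np.asarray(ln.coords)
            segs.extend(zip(xy[:-1], xy[1:]))
        a = np.array([s[0] for s in segs])  # (S, 2)
        b = np.array([s[1] for s in segs])
        cols, rows = np.meshgrid(np.arange(n_px), np.arange(n_px))
        pts = np.stack(
            [(cols + 0.5) * px - half, (rows + 0.5) * px - half], axis=-1
        ).reshape(-1, 1, 2)
        ab = (b - a)[None]
        t = np.clip(
            ((pts - a[None]) * ab).sum(-1) / (ab * ab).sum(-1), 0.0, 1.0
        )
        proj = a[None] + t[..., None] * ab
        dmin = np.sqrt(((pts - proj) ** 2).sum(-1)).min(axis=1).reshape(n_px, n_px)

        # fiber clip: inside the disc polygon or within half_w of its rim
        ex = np.asarray(geom.fiber_polygon.exterior.coords)
        ea, eb = ex[:-1], ex[1:]
        eab = (eb - ea)[None]
        et = np.clip(
            ((pts - ea[None]) * eab).sum(-1) / (eab * eab).sum(-1), 0.0, 1.0
        )
        eproj = ea[None] + et[..., None] * eab
        rim = np.sqrt(((pts - eproj) ** 2).sum(-1)).min(axis=1).reshape(n_px, n_px)
        centers = pts.reshape(n_px, n_px, 2)
        inside = (centers**2).sum(-1) <= (
            np.sqrt((ex**2).sum(1)).min() ** 2
        )  # conservative inner radius
        in_fiber = inside | (rim <= half_w)

        oracle = (dmin <= half_w) & in_fiber
        assert np.array_equal(gt.boundary_mask, oracle)
        amp = clean_spec.background + clean_spec.boundary_amp * oracle
        assert np.array_equal(stack.plane("serca", 0), np.round(amp).astype(np.uint16))

    def test_bit_exact_reproducibility(self, small_spec, small_geometry):
        s1, _ = fimid.render_stack(small_geometry, small_spec)
        s2, _ = fimid.render_stack(small_geometry, small_spec)
        assert np.array_equal(s1.data, s2.data)

    def test_glycolytic_fiber_has_no_puncta(self):
        spec = SyntheticSpec(seed=5, oxidative=False, **SMALL, **CLEAN)
        stack, gt = fimid.render_stack(fimid.generate_geometry(spec), spec)
        assert len(gt.puncta_xy_um) == 0
        # autofluorescence never exceeds background + faint decoration
        assert stack.plane("auto", 0).max() <= np.ceil(
            spec.background + spec.auto_faint_amp
        )

    def test_oxidative_fiber_has_puncta(self):
        spec = SyntheticSpec(seed=5, oxidative=True, **SMALL, **CLEAN)
        stack, gt = fimid.render_stack(fimid.generate_geometry(spec), spec)
        assert len(gt.puncta_xy_um) == spec.puncta_per_fiber
        assert stack.plane("auto", 0).max() > spec.puncta_amp / 2

    def test_middle_plane_most_in_focus(self):
        spec = SyntheticSpec(seed=9, n_planes=7, **SMALL)
        stack, _ = fimid.render_stack(fimid.generate_geometry(spec), spec)
        assert fimid.select_focus_plane(stack, "serca") == 3

    def test_area_conservation_and_mean_cell_area(self, small_render, small_spec):
        _, gt = small_render
        total = gt.areas_um2.sum() + gt.boundary_area_um2
        assert total == pytest.approx(gt.fiber_area_um2, rel=1e-9)
        boundary_fraction = gt.boundary_area_um2 / gt.fiber_area_um2
        expected_mean = (
            gt.fiber_area_um2 * (1 - boundary_fraction) / small_spec.n_myofibrils
        )
        assert gt.areas_um2.mean() == pytest.approx(expected_mean, rel=0.05)


class TestMosaic:
    def test_two_fiber_mosaic_masks_disjoint(self):
        specs = [
            fimid.SyntheticSpec(seed=s, n_myofibrils=40, fiber_radius_um=5.0)
            for s in (1, 2)
        ]
        stack, truths = fimid.render_mosaic(specs, seed=3)
        assert len(truths) == 2
        assert not (truths[0].fiber_mask & truths[1].fiber_mask).any()
        assert truths[0].fiber_mask.shape == stack.shape_yx


class TestGroundTruthTable:
    def test_table_matches_shoelace_and_counts(self, small_geometry, small_render):
        _, gt = small_render
        table = fimid.ground_truth_table(gt)
        myo = table[table["kind"] == "myofibril"]
        assert len(myo) == gt.true_count
        for i, interior in enumerate(small_geometry.interiors):
            expected = shoelace(np.asarray(interior.exterior.coords)) - sum(
                shoelace(np.asarray(ring.coords)) for ring in interior.interiors
            )
            assert myo.iloc[i]["area_um2"] == pytest.approx(expected, rel=1e-9)
        summary = table[table["kind"] == "fiber"].iloc[0]
        assert summary["true_count"] == gt.true_count
        assert summary["area_um2"] >= myo["area_um2"].sum()
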