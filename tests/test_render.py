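"""Deterministic rendering: windowing, slicing, overlays, page flattening."""

import numpy as np
import pytest

from scanqc.render import (GUTTER, MARGIN, PANEL, AnnotationSpec, OverlaySpec,
                           RenderRecipe, SlicePlan, flatten_pages,
                           format_annotation_lines, label_palette,
                           load_canonical, normalize_intensity, plan_slices,
                           render_overlay, render_recipe, render_scalar_grid,
                           render_side_by_side, render_triplanar, save_png)


def sphere(shape=(48, 48, 48), radius=0.35):
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    c = [(s - 1) / 2 for s in shape]
    d2 = sum(((g - ci) / s) ** 2 for g, ci, s in zip(grids, c, shape))
    return (d2 < radius ** 2).astype(float) * 100.0


class TestNormalizeIntensity:
    def test_constant_volume_maps_to_zeros(self):
        vol = np.full((8, 8, 8), 7.0)
        assert np.all(normalize_intensity(vol) == 0.0)

    def test_linear_ramp_pins_percentile_window(self):
        vol = np.linspace(0, 1000, 64 ** 3).reshape(64, 64, 64)
        out = normalize_intensity(vol)
        p1, p99 = np.percentile(vol, [1, 99])
        assert np.all(out[vol <= p1] == 0.0)
        assert np.all(out[vol >= p99] == 1.0)
        mid = (vol > p1) & (vol < p99)
        expected = (vol[mid] - p1) / (p99 - p1)
        np.testing.assert_allclose(out[mid], expected, atol=1e-12)

    def test_output_range_property(self, rng):
        for _ in range(5):
            vol = rng.normal(size=(12, 12, 12)) * rng.uniform(0.1, 100)
            out = normalize_intensity(vol)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_volume_is_error(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.empty((0, 4, 4)))


class TestPlanSlices:
    def test_fraction_arithmetic(self):
        idx = plan_slices((100, 100, 100), SlicePlan((0.3, 0.5, 0.7)))
        assert np.all(idx == [[30, 50, 70]] * 3)

    def test_singleton_dims_clamp_to_zero(self):
        idx = plan_slices((1, 1, 1), SlicePlan())
        assert np.all(idx == 0)

    def test_indices_always_in_range(self, rng):
        for _ in range(20):
            shape = tuple(int(x) for x in rng.integers(1, 200, size=3))
            idx = plan_slices(shape, SlicePlan())
            for ax in range(3):
                assert np.all(idx[ax] >= 0) and np.all(idx[ax] < shape[ax])

    def test_slice_plan_validation(self):
        with pytest.raises(ValueError):
            SlicePlan((0.5, 0.3, 0.7))
        with pytest.raises(ValueError):
            SlicePlan((0.0, 0.5, 0.7))


class TestTriplanar:
    def test_zero_volume_renders_background_only(self):
        canvas = render_triplanar(np.zeros((64, 64, 64)))
        assert np.all(canvas == canvas.flat[0])

    def test_sphere_populates_all_nine_panels(self):
        canvas = render_triplanar(sphere())
        for r in range(3):
            for c in range(3):
                y = MARGIN + r * (PANEL + GUTTER)
                x = MARGIN + c * (PANEL + GUTTER)
                panel = canvas[y:y + PANEL, x:x + PANEL]
                assert panel.max() > 0, f"panel ({r},{c}) is empty"

    def test_repeated_renders_are_identical(self, small_spec):
        from scanqc.synth_fixtures import make_t1_phantom
        vol = np.asarray(make_t1_phantom(small_spec).dataobj)
        a, b = render_triplanar(vol), render_triplanar(vol)
        np.testing.assert_array_equal(a, b)

    def test_4d_input_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            render_triplanar(np.zeros((8, 8, 8, 4)))


class TestOverlay:
    def test_alpha_zero_equals_plain_triplanar(self):
        base = sphere()
        labels = (sphere(radius=0.2) > 0).astype(int)
        out = render_overlay(base, labels, OverlaySpec(alpha=0.0))
        np.testing.assert_array_equal(out, render_triplanar(base))

    def test_alpha_one_single_label_shows_pure_palette_color(self):
        base = sphere()
        labels = np.full(base.shape, 3, dtype=int)
        out = render_overlay(base, labels, OverlaySpec(alpha=1.0))
        color = np.array(label_palette(3)) / 255.0
        y = MARGIN + PANEL // 2
        x = MARGIN + PANEL // 2
        np.testing.assert_allclose(out[y, x], color, atol=1e-9)

    def test_blend_formula_half_alpha(self):
        """Blended pixel = 0.5*gray + 0.5*palette at alpha 0.5."""
        base = np.linspace(0.0, 1000.0, 32 ** 3).reshape(32, 32, 32)
        labels = np.full(base.shape, 5, dtype=int)
        alpha = 0.5
        out = render_overlay(base, labels, OverlaySpec(alpha=alpha))
        gray = render_triplanar(base)[..., 0]
        color = np.array(label_palette(5)) / 255.0
        y = MARGIN + PANEL // 2
        x = MARGIN + PANEL // 2
        expected = (1 - alpha) * gray[y, x] + alpha * color
        np.testing.assert_allclose(out[y, x], expected, atol=1e-9)

    def test_background_label_untouched(self):
        base = sphere()
        labels = np.zeros(base.shape, dtype=int)
        out = render_overlay(base, labels, OverlaySpec(alpha=0.9))
        np.testing.assert_array_equal(out, render_triplanar(base))

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"16.*24"):
            render_overlay(np.zeros((16, 16, 16)), np.zeros((24, 24, 24)),
                           OverlaySpec())


class TestSideBySide:
    def test_identical_inputs_give_identical_halves(self):
        vol = sphere()
        canvas = render_side_by_side(vol, vol)
        single_w = (canvas.shape[1] - GUTTER) // 2
        np.testing.assert_array_equal(canvas[:, :single_w],
                                      canvas[:, single_w + GUTTER:])

    def test_darker_right_input_renders_darker(self):
        vol = sphere()
        canvas = render_side_by_side(vol, vol / 2)
        single_w = (canvas.shape[1] - GUTTER) // 2
        assert canvas[:, single_w + GUTTER:].mean() < canvas[:, :single_w].mean()

    def test_canvas_width_is_two_grids_plus_gutter(self):
        vol = sphere((24, 24, 24))
        single = render_triplanar(vol)
        canvas = render_side_by_side(vol, vol)
        assert canvas.shape[1] == 2 * single.shape[1] + GUTTER


class TestScalarGrid:
    def test_single_map_layout_and_window(self):
        vol = sphere()
        canvas, windows = render_scalar_grid([("FA", vol)])
        assert len(windows) == 1
        name, lo, hi = windows[0]
        p1, p99 = np.percentile(vol, [1, 99])
        assert (name, lo, hi) == ("FA", p1, p99)

    def test_three_maps_render_in_input_order(self):
        vols = [("FA", sphere()), ("MD", sphere() * 2), ("RD", sphere() * 3)]
        canvas, windows = render_scalar_grid(vols)
        assert [w[0] for w in windows] == ["FA", "MD", "RD"]
        rows = 3
        assert canvas.shape[0] == 2 * MARGIN + rows * PANEL + (rows - 1) * GUTTER


class TestFlattenPages:
    def test_single_page_identity(self, rng):
        page = rng.random((40, 60, 3))
        np.testing.assert_array_equal(flatten_pages([page]), page)

    def test_height_additivity(self, rng):
        pages = [rng.random((100, 50, 3)), rng.random((150, 50, 3))]
        out = flatten_pages(pages)
        assert out.shape[0] == 250 and out.shape[1] == 50

    def test_narrow_page_centered_on_background(self):
        wide = np.ones((10, 300, 3))
        narrow = np.ones((10, 200, 3))
        out = flatten_pages([wide, narrow])
        assert out.shape == (20, 300, 3)
        band = out[10:, :, :]
        assert np.all(band[:, :50] == 0) and np.all(band[:, 250:] == 0)
        assert np.all(band[:, 50:250] == 1)

    def test_height_additivity_property(self, rng):
        pages = [rng.random((int(rng.integers(5, 40)), int(rng.integers(5, 40)), 3))
                 for _ in range(int(rng.integers(1, 6)))]
        assert flatten_pages(pages).shape[0] == sum(p.shape[0] for p in pages)


class TestRecipeDispatch:
    def test_unknown_recipe_name_rejected(self):
        with pytest.raises(ValueError, match="unknown recipe"):
            RenderRecipe(name="mystery")

    def test_missing_input_role_is_arity_error(self, tmp_path):
        recipe = RenderRecipe(name="seg_overlay")
        with pytest.raises(ValueError, match="base"):
            render_recipe(recipe, {}, str(tmp_path / "x.png"))

    def test_seg_overlay_writes_decodable_png(self, tmp_path, small_spec):
        from PIL import Image
        from scanqc.synth_fixtures import make_labelmap, make_t1_phantom
        base = np.asarray(make_t1_phantom(small_spec).dataobj)
        labels = np.asarray(make_labelmap(small_spec, 5).dataobj)
        out = tmp_path / "seg.png"
        render_recipe(RenderRecipe(name="seg_overlay"),
                      {"base": base, "labels": labels}, str(out))
        assert out.stat().st_size > 0
        img = Image.open(out)
        assert img.size[0] == 2 * MARGIN + 3 * PANEL + 2 * GUTTER

    def test_streamline_count_appears_in_annotation(self):
        spec = AnnotationSpec(metrics=(("streamlines", 12034, ""),))
        lines = format_annotation_lines(spec)
        assert any("12034" in l for l in lines)

    def test_passthrough_preserves_bytes(self, tmp_path, rng):
        src = tmp_path / "pipeline_qc.png"
        save_png(rng.integers(0, 255, (20, 20, 3)).astype(np.uint8), str(src))
        out = tmp_path / "out.png"
        render_recipe(RenderRecipe(name="generic_png_passthrough"),
                      {"png": str(src)}, str(out))
        assert out.read_bytes() == src.read_bytes()

    def test_raw_dwi_reduces_4d_and_notes_volume_count(self, tmp_path, small_spec):
        from scanqc.synth_fixtures import make_dwi_phantom
        img, _, _ = make_dwi_phantom(small_spec, 8)
        out1, out2 = tmp_path / "a.png", tmp_path / "b.png"
        vol = np.asarray(img.dataobj)
        render_recipe(RenderRecipe(name="raw_dwi"), {"volume": vol}, str(out1))
        render_recipe(RenderRecipe(name="raw_dwi"), {"volume": vol[..., :1]}, str(out2))
        # annotation band differs (8 volumes vs 1) even though volume 0 is shown
        assert out1.read_bytes() != out2.read_bytes()

    def test_rerender_is_byte_identical(self, tmp_path, small_spec):
        from scanqc.synth_fixtures import make_t1_phantom
        vol = np.asarray(make_t1_phantom(small_spec).dataobj)
        out = tmp_path / "t1.png"
        recipe = RenderRecipe(name="raw_t1w",
                              annotation=AnnotationSpec(metrics=(("wbv", 123.4, "ml"),)))
        render_recipe(recipe, {"volume": vol}, str(out))
        first = out.read_bytes()
        render_recipe(recipe, {"volume": vol}, str(out))
        assert out.read_bytes() == first


def test_orientation_stability(tmp_path, small_spec):
    """Axis-permuted volumes with matching affines render identically."""
    import nibabel as nib
    from scanqc.synth_fixtures import make_t1_phantom
    img = make_t1_phantom(small_spec)
    p1 = tmp_path / "ras.nii.gz"
    nib.save(img, p1)
    # permute axes to (z, x, y); new affine columns follow the old axes
    data = np.transpose(np.asarray(img.dataobj), (2, 0, 1))
    affine = img.affine[:, [2, 0, 1, 3]]
    p2 = tmp_path / "permuted.nii.gz"
    nib.save(nib.Nifti1Image(data, affine), p2)
    np.testing.assert_array_equal(
        render_triplanar(load_canonical(str(p1))),
        render_triplanar(load_canonical(str(p2))))
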