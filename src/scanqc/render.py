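"""Deterministic QC-PNG generation from volumes, overlays and page stacks.

Every pipeline output is condensed to a single lossless PNG so a reviewer can
judge it at a glance: tri-planar (axial/coronal/sagittal) slice grids for
structural volumes, label-map overlays on T1w or FA backdrops, side-by-side
grids for before/after comparisons (e.g. free-water correction), axial rows
of scalar parameter maps with colorbars, and vertical flattening of
multi-page QC documents into one image.  Quantitative annotations (tissue
volumes, streamline counts, ...) are printed in a text band under the image
area.

Rendering is a pure function of its inputs: fixed canvas geometry, an
embedded bitmap font, a fixed 256-entry label palette and metadata-free PNG
output make repeated runs byte-identical.  Volumes are reoriented to
canonical RAS before slicing, so axis permutations of the input (with
matching affine changes) do not change the raster.
"""

from __future__ import annotations

import colorsys
import os
import shutil
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
from PIL import Image, ImageDraw, ImageFont

__all__ = [
    "SlicePlan",
    "OverlaySpec",
    "AnnotationSpec",
    "RenderRecipe",
    "RECIPE_NAMES",
    "normalize_intensity",
    "plan_slices",
    "render_triplanar",
    "render_overlay",
    "render_side_by_side",
    "render_scalar_grid",
    "flatten_pages",
    "render_recipe",
    "format_annotation_lines",
    "label_palette",
    "load_canonical",
    "save_png",
]

# ---------------------------------------------------------------- geometry

PANEL = 160          # each slice panel is resampled to PANEL x PANEL pixels
GUTTER = 8           # spacing between panels and between side-by-side grids
MARGIN = 8           # outer margin
ANNOT_LINE = 14      # height of one annotation text line
COLORBAR_W = 24      # width of a vertical colorbar strip
BACKGROUND = 0       # canvas background gray level

RECIPE_NAMES = (
    "raw_t1w",
    "raw_dwi",
    "tensor_atlas_overlay",
    "seg_overlay",
    "freewater_side_by_side",
    "bundle_overlay",
    "skullstrip",
    "scalar_maps_axial",
    "flatten_pages",
    "generic_png_passthrough",
)


@dataclass(frozen=True)
class SlicePlan:
    """Slice positions as volume fractions, shared by all three planes."""

    fractions: tuple[float, float, float] = (0.3, 0.5, 0.7)

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.fractions)
        if len(f) != 3:
            raise ValueError("exactly three slice fractions required")
        if not all(0.0 < x < 1.0 for x in f):
            raise ValueError(f"fractions must lie in (0,1): {f}")
        if not (f[0] < f[1] < f[2]):
            raise ValueError(f"fractions must be strictly increasing: {f}")
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class OverlaySpec:
    """How a label map is blended onto a grayscale base image."""

    alpha: float = 0.5
    background_label: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1]: {self.alpha}")


@dataclass(frozen=True)
class AnnotationSpec:
    """Quantitative annotations printed on the canvas.

    ``metrics`` render as ``name: value unit`` lines in the given order;
    ``colorbar`` (min, max) attaches an intensity colorbar, present only when
    min < max.
    """

    metrics: tuple[tuple[str, float, str], ...] = ()
    colorbar: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metrics", tuple((str(n), v, str(u)) for n, v, u in self.metrics))
        if self.colorbar is not None and not self.colorbar[0] < self.colorbar[1]:
            object.__setattr__(self, "colorbar", None)


@dataclass(frozen=True)
class RenderRecipe:
    """Declarative description of how one pipeline output becomes a PNG."""

    name: str
    slice_plan: SlicePlan = field(default_factory=SlicePlan)
    overlay: OverlaySpec = field(default_factory=OverlaySpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)

    def __post_init__(self) -> None:
        if self.name not in RECIPE_NAMES:
            raise ValueError(
                f"unknown recipe {self.name!r}; known: {', '.join(RECIPE_NAMES)}")


# ------------------------------------------------------------- primitives

def normalize_intensity(volume: np.ndarray,
                        window: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Map a scalar grid to display range [0, 1].

    The [p1, p99] percentile window (robust to hot voxels) is mapped linearly
    to [0, 1] and clipped.  A degenerate window — constant volume — maps to
    all zeros.  An explicit ``window`` overrides the percentiles (used for
    shared windows in comparisons).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.size == 0:
        raise ValueError("empty volume")
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    if window is None:
        lo, hi = np.percentile(vol, [1.0, 99.0])
    else:
        lo, hi = window
    if hi <= lo:
        return np.zeros_like(vol)
    return np.clip((vol - lo) / (hi - lo), 0.0, 1.0)


def display_window(volume: np.ndarray) -> tuple[float, float]:
    """The [p1, p99] window :func:`normalize_intensity` would use."""
    lo, hi = np.percentile(np.asarray(volume, dtype=float), [1.0, 99.0])
    return float(lo), float(hi)


def plan_slices(shape: Sequence[int], plan: SlicePlan) -> np.ndarray:
    """Integer slice indices, 3 axes x 3 slices: floor(fraction*dim), clamped."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"need a 3D shape with positive dims, got {shape}")
    idx = np.empty((3, 3), dtype=int)
    for ax, dim in enumerate(shape):
        for j, frac in enumerate(plan.fractions):
            idx[ax, j] = min(max(int(np.floor(frac * dim)), 0), dim - 1)
    return idx


def label_palette(label: int) -> tuple[int, int, int]:
    """Fixed 256-entry label palette, indexed by label id mod 256.

    Hues step around the color wheel by the golden ratio so nearby label ids
    get visually distinct colors; the mapping is a pure function of the id,
    hence stable across runs and machines.
    """
    i = int(label) % 256
    hue = (i * 0.6180339887498949) % 1.0
    sat = 0.85 if i % 2 == 0 else 0.65
    val = 0.95 if i % 3 != 0 else 0.75
    r, g, b = colorsys.hsv_to_rgb(hue, sat, val)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


def _palette_lut() -> np.ndarray:
    lut = np.array([label_palette(i) for i in range(256)], dtype=float) / 255.0
    return lut


_LUT = _palette_lut()


def _extract_slice(vol: np.ndarray, axis: int, index: int) -> np.ndarray:
    """One 2D display slice from a RAS volume.

    axis 0 = axial (fixed z -> row), 1 = coronal (fixed y), 2 = sagittal
    (fixed x).  Slices are arranged with the subject's left at the image left
    (neurological convention) and superior/anterior at the top.
    """
    if axis == 0:      # axial: (x, y) plane at z=index
        sl = vol[:, :, index]        # (X, Y)
        return sl.T[::-1, :]         # rows: anterior->posterior top-down
    if axis == 1:      # coronal: (x, z) plane at y=index
        sl = vol[:, index, :]        # (X, Z)
        return sl.T[::-1, :]         # rows: superior at top
    if axis == 2:      # sagittal: (y, z) plane at x=index
        sl = vol[index, :, :]        # (Y, Z)
        return sl.T[::-1, :]
    raise ValueError(f"axis must be 0, 1 or 2, got {axis}")


def _resample_panel(img2d: np.ndarray) -> np.ndarray:
    """Nearest-neighbor resample of a 2D (gray or RGB) slice to PANEL**2."""
    h, w = img2d.shape[:2]
    rows = (np.arange(PANEL) * h) // PANEL
    cols = (np.arange(PANEL) * w) // PANEL
    return img2d[np.ix_(rows, cols)]


def _grid_canvas(n_rows: int, n_cols: int, extra_h: int = 0,
                 extra_w: int = 0) -> np.ndarray:
    h = 2 * MARGIN + n_rows * PANEL + (n_rows - 1) * GUTTER + extra_h
    w = 2 * MARGIN + n_cols * PANEL + (n_cols - 1) * GUTTER + extra_w
    canvas = np.full((h, w, 3), BACKGROUND / 255.0, dtype=float)
    return canvas

def _place_panel(canvas: np.ndarray, row: int, col: int, panel: np.ndarray) -> None:
    y = MARGIN + row * (PANEL + GUTTER)
    x = MARGIN + col * (PANEL + GUTTER)
    if panel.ndim == 2:
        panel = np.repeat(panel[:, :, None], 3, axis=2)
    canvas[y:y + PANEL, x:x + PANEL, :] = panel


def _triplanar_panels(display: np.ndarray, plan: SlicePlan) -> list[list[np.ndarray]]:
    """9 resampled panels (3 planes x 3 slices) from a display-range volume."""
    idx = plan_slices(display.shape[:3], plan)
    panels = []
    for ax in range(3):
        # plan_slices rows are (x, y, z) dims; display axes map axial->z etc.
        dim_axis = {0: 2, 1: 1, 2: 0}[ax]
        panels.append([
            _resample_panel(_extract_slice(display, ax, idx[dim_axis, j]))
            for j in range(3)
        ])
    return panels


def _grid_from_display(display: np.ndarray, plan: SlicePlan) -> np.ndarray:
    canvas = _grid_canvas(3, 3)
    for r, row_panels in enumerate(_triplanar_panels(display, plan)):
        for c, panel in enumerate(row_panels):
            _place_panel(canvas, r, c, panel)
    return canvas


def render_triplanar(volume: np.ndarray, plan: SlicePlan = SlicePlan()) -> np.ndarray:
    """Tri-planar raster: rows axial/coronal/sagittal, 3 slice columns.

    ``volume`` is a 3D scalar grid in canonical RAS order.  Returns a float
    RGB canvas in [0, 1] of fixed size for a given plan.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"render_triplanar needs a 3D volume, got shape {vol.shape}")
    return _grid_from_display(normalize_intensity(vol), plan)


def render_overlay(base: np.ndarray, labelmap: np.ndarray, spec: OverlaySpec,
                   plan: SlicePlan = SlicePlan()) -> np.ndarray:
    """Tri-planar raster of a label map alpha-blended onto a grayscale base.

    Per pixel with label l != background:
    ``out = (1 - alpha) * gray(base) + alpha * palette(l)``;
    background pixels show the base unmodified.
    """
    base = np.asarray(base, dtype=float)
    labels = np.asarray(labelmap)
    if base.shape != labels.shape:
        raise ValueError(
            f"base shape {base.shape} != labelmap shape {labels.shape}")
    display = normalize_intensity(base)
    canvas = _grid_canvas(3, 3)
    idx = plan_slices(display.shape, plan)
    for ax in range(3):
        dim_axis = {0: 2, 1: 1, 2: 0}[ax]
        for j in range(3):
            k = idx[dim_axis, j]
            g = _resample_panel(_extract_slice(display, ax, k))
            lab = _resample_panel(_extract_slice(labels, ax, k)).astype(int)
            rgb = np.repeat(g[:, :, None], 3, axis=2)
            fg = lab != spec.background_label
            colors = _LUT[np.mod(lab, 256)]
            rgb[fg] = (1.0 - spec.alpha) * rgb[fg] + spec.alpha * colors[fg]
            _place_panel(canvas, ax, j, rgb)
    return canvas


def render_side_by_side(volume_a: np.ndarray, volume_b: np.ndarray,
                        plan: SlicePlan = SlicePlan()) -> np.ndarray:
    """Two tri-planar grids on one canvas, a left and b right.

    Both halves share the intensity window computed from ``a`` so a
    before/after pair (e.g. uncorrected vs free-water-corrected FA) is
    directly comparable.
    """
    a = np.asarray(volume_a, dtype=float)
    b = np.asarray(volume_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    window = display_window(a)
    left = _grid_from_display(normalize_intensity(a, window=window), plan)
    right = _grid_from_display(normalize_intensity(b, window=window), plan)
    gutter = np.full((left.shape[0], GUTTER, 3), BACKGROUND / 255.0, dtype=float)
    return np.concatenate([left, gutter, right], axis=1)


def _colorbar_strip(height: int) -> np.ndarray:
    """Vertical grayscale gradient, max at top."""
    g = np.linspace(1.0, 0.0, height)
    strip = np.repeat(np.repeat(g[:, None], COLORBAR_W, axis=1)[:, :, None], 3, axis=2)
    return strip


def render_scalar_grid(maps: Sequence[tuple[str, np.ndarray]],
                       plan: SlicePlan = SlicePlan()) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    """One row per scalar map, three axial slices each, plus a colorbar.

    Returns the canvas and, per map, the (name, window_min, window_max) its
    colorbar spans — the same [p1, p99] display window used for rendering.
    """
    if not maps:
        raise ValueError("at least one map required")
    shapes = {np.asarray(v).shape for _, v in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps must share a shape, got {sorted(map(str, shapes))}")
    n = len(maps)
    canvas = _grid_canvas(n, 3, extra_w=GUTTER + COLORBAR_W)
    windows: list[tuple[str, float, float]] = []
    for r, (name, vol) in enumerate(maps):
        vol = np.asarray(vol, dtype=float)
        lo, hi = display_window(vol)
        windows.append((name, lo, hi))
        display = normalize_intensity(vol)
        idx = plan_slices(vol.shape, plan)
        for j in range(3):
            panel = _resample_panel(_extract_slice(display, 0, idx[2, j]))
            _place_panel(canvas, r, j, panel)
        y = MARGIN + r * (PANEL + GUTTER)
        x = MARGIN + 3 * (PANEL + GUTTER) + GUTTER
        canvas[y:y + PANEL, x:x + COLORBAR_W, :] = _colorbar_strip(PANEL)
    return canvas, windows


def flatten_pages(pages: Sequence[np.ndarray]) -> np.ndarray:
    """Stack page rasters vertically into a single image.

    Pages keep their order; narrower pages are centered on background
    padding; total height is the sum of page heights.
    """
    if len(pages) == 0:
        raise ValueError("at least one page required")
    rasters = []
    for p in pages:
        p = np.asarray(p, dtype=float)
        if p.ndim == 2:
            p = np.repeat(p[:, :, None], 3, axis=2)
        rasters.append(p)
    width = max(p.shape[1] for p in rasters)
    total_h = sum(p.shape[0] for p in rasters)
    out = np.full((total_h, width, 3), BACKGROUND / 255.0, dtype=float)
    y = 0
    for p in rasters:
        h, w = p.shape[:2]
        x = (width - w) // 2
        out[y:y + h, x:x + w, :] = p
        y += h
    return out


# --------------------------------------------------------- PNG assembly

def _font() -> ImageFont.ImageFont:
    return ImageFont.load_default()  # embedded bitmap font: deterministic


def format_annotation_lines(annotation: AnnotationSpec,
                            extra_lines: Sequence[str] = ()) -> list[str]:
    """Text lines of the annotation band, in render order."""
    lines = list(extra_lines)
    for name, value, unit in annotation.metrics:
        if isinstance(value, float) and not float(value).is_integer():
            text_val = f"{value:.4g}"
        else:
            text_val = str(int(value)) if isinstance(value, (int, float)) else str(value)
        lines.append(f"{name}: {text_val}{' ' + unit if unit else ''}")
    if annotation.colorbar is not None:
        lo, hi = annotation.colorbar
        lines.append(f"colorbar: [{lo:.4g}, {hi:.4g}]")
    return lines


def _annotate(canvas: np.ndarray, annotation: AnnotationSpec,
              extra_lines: Sequence[str] = ()) -> Image.Image:
    """Attach a text band below the image area and return a PIL image."""
    lines = format_annotation_lines(annotation, extra_lines)
    band_h = ANNOT_LINE * len(lines) + (MARGIN if lines else 0)
    arr = np.clip(canvas * 255.0, 0, 255).astype(np.uint8)
    h, w = arr.shape[:2]
    img = Image.new("RGB", (w, h + band_h), (BACKGROUND,) * 3)
    img.paste(Image.fromarray(arr), (0, 0))
    if lines:
        draw = ImageDraw.Draw(img)
        font = _font()
        for i, line in enumerate(lines):
            draw.text((MARGIN, h + i * ANNOT_LINE), line, fill=(230, 230, 230), font=font)
    return img


def save_png(image, out_path: str) -> None:
    """Write a PNG with no ancillary metadata (no timestamps: deterministic)."""
    if isinstance(image, np.ndarray):
        arr = image
        if arr.dtype != np.uint8:
            arr = np.clip(np.asarray(arr, dtype=float) * 255.0, 0, 255).astype(np.uint8)
        image = Image.fromarray(arr)
    os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
    tmp = out_path + ".tmp"
    image.save(tmp, format="PNG", pnginfo=None)
    os.replace(tmp, out_path)


def load_canonical(path: str) -> np.ndarray:
    """Load a NIfTI volume reoriented to canonical RAS axis order."""
    img = nib.as_closest_canonical(nib.load(path))
    return np.asanyarray(img.dataobj).astype(float)


def _as_volume(v) -> np.ndarray:
    if isinstance(v, (str, os.PathLike)):
        return load_canonical(os.fspath(v))
    return np.asarray(v, dtype=float)


def render_recipe(recipe: RenderRecipe, inputs: Mapping[str, object],
                  out_path: str) -> str:
    """Dispatch a recipe to the primitives above and write a single PNG.

    ``inputs`` maps role names to volumes (arrays or NIfTI paths), page
    rasters, or PNG paths depending on the recipe:

    ==========================  ==========================================
    recipe                      required roles
    ==========================  ==========================================
    raw_t1w / skullstrip        ``volume``
    raw_dwi                     ``volume`` (4D; volume 0 shown, count noted)
    tensor_atlas_overlay        ``base`` (FA map), ``labels``
    seg_overlay                 ``base`` (T1w), ``labels``
    bundle_overlay              ``base`` (FA map), ``labels`` (bundle mask)
    freewater_side_by_side      ``a`` (uncorrected), ``b`` (corrected)
    scalar_maps_axial           ``maps``: list of (name, volume)
    flatten_pages               ``pages``: list of rasters or PNG paths
    generic_png_passthrough     ``png``: path to a pipeline-provided PNG
    ==========================  ==========================================

    Re-invocation on identical inputs overwrites the output byte-identically.
    Returns ``out_path``.
    """
    def need(role: str):
        if role not in inputs:
            raise ValueError(f"recipe {recipe.name!r} requires input role {role!r}")
        return inputs[role]

    extra_lines: list[str] = []
    annotation = recipe.annotation

    if recipe.name == "generic_png_passthrough":
        src = os.fspath(need("png"))
        os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
        tmp = out_path + ".tmp"
        shutil.copyfile(src, tmp)
        os.replace(tmp, out_path)
        return out_path

    if recipe.name in ("raw_t1w", "skullstrip"):
        canvas = render_triplanar(_as_volume(need("volume")), recipe.slice_plan)
    elif recipe.name == "raw_dwi":
        vol = _as_volume(need("volume"))
        if vol.ndim == 4:
            extra_lines.append(f"volumes: {vol.shape[3]}")
            vol = vol[..., 0]
        canvas = render_triplanar(vol, recipe.slice_plan)
    elif recipe.name in ("tensor_atlas_overlay", "seg_overlay", "bundle_overlay"):
        canvas = render_overlay(_as_volume(need("base")), _as_volume(need("labels")),
                                recipe.overlay, recipe.slice_plan)
    elif recipe.name == "freewater_side_by_side":
        canvas = render_side_by_side(_as_volume(need("a")), _as_volume(need("b")),
                                     recipe.slice_plan)
    elif recipe.name == "scalar_maps_axial":
        maps = [(name, _as_volume(v)) for name, v in need("maps")]
        canvas, windows = render_scalar_grid(maps, recipe.slice_plan)
        for name, lo, hi in windows:
            extra_lines.append(f"{name} window: [{lo:.4g}, {hi:.4g}]")
    elif recipe.name == "flatten_pages":
        pages = []
        for p in need("pages"):
            if isinstance(p, (str, os.PathLike)):
                pages.append(np.asarray(Image.open(p).convert("RGB"), dtype=float) / 255.0)
            else:
                pages.append(np.asarray(p, dtype=float))
        canvas = flatten_pages(pages)
    else:  # pragma: no cover - guarded by RenderRecipe validation
        raise ValueError(f"unknown recipe: {recipe.name!r}")

    img = _annotate(canvas, annotation, extra_lines)
    save_png(img, out_path)
    return out_path
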