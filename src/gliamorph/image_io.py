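"""Reading calibrated channels and ROIs; writing tables, overlays, previews.

TIFF stacks are collapsed by maximum-intensity projection on read. Result
tables are always written as plain CSV (one file per section) plus a single
XLSX workbook with sheets ``single_cells``, ``clusters``, ``combined`` and
``histograms``. ROI polygons travel as a small JSON document::

    {"polygons": [{"vertices": [[r, c], ...]}, ...]}

with 0-based (row, col) vertices at pixel centers.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon
from skimage.morphology import disk, erosion
from skimage.transform import downscale_local_mean, resize

from .datatypes import (
    CLASS_COLORS,
    CalibratedImage,
    ChannelSet,
    GliaComponent,
    MorphometryRecord,
    RECORD_COLUMNS,
    RatioHistogram,
    RoiPolygon,
)

HISTOGRAM_COLUMNS = ["stratum", "bin_left", "bin_right", "count"]


def read_channel(
    path: str | os.PathLike,
    pixel_size_um: float,
    modality: str = "fluorescence",
    role: str = "glia_marker",
) -> CalibratedImage:
    """Read a single- or multi-page grayscale image as a calibrated channel.

    Multi-page (z-stack) TIFFs are collapsed by per-pixel maximum before
    return; intensities are preserved without rescaling.
    """
    if not (float(pixel_size_um) > 0):
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"cannot read image file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(path)
        else:
            data = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and path.suffix.lower() not in (
        ".tif",
        ".tiff",
    ):
        # grayscale PNG saved as RGB(A): collapse identical channels
        data = data[..., 0]
    data = max_project(data)
    if data.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    return CalibratedImage(data, pixel_size_um, modality=modality, role=role)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Collapse a (pages, h, w) stack by per-pixel maximum; 2D passes through.

    Idempotent: projecting an already 2D image returns it unchanged.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim == 3:
        return stack.max(axis=0)
    raise ValueError(f"expected 2D image or 3D stack, got shape {stack.shape}")


# ---------------------------------------------------------------------------
# ROI polygons


def read_rois(path: str | os.PathLike) -> list[RoiPolygon]:
    with open(path) as fh:
        doc = json.load(fh)
    return [RoiPolygon(np.asarray(p["vertices"], float)) for p in doc["polygons"]]


def write_rois(rois: Sequence[RoiPolygon], path: str | os.PathLike) -> None:
    doc = {"polygons": [{"vertices": r.vertices.tolist()} for r in rois]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon: a pixel is set iff its center lies in or on the
    polygon boundary."""
    poly = Polygon([(c, r) for r, c in roi.vertices])  # shapely is (x, y)
    if not poly.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area == 0:
        raise ValueError("degenerate polygon with zero area")
    mask = np.zeros(shape, dtype=bool)
    minc, minr, maxc, maxr = poly.bounds
    r0 = max(int(np.floor(minr)), 0)
    r1 = min(int(np.ceil(maxr)), shape[0] - 1)
    c0 = max(int(np.floor(minc)), 0)
    c1 = min(int(np.ceil(maxc)), shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return mask


# ---------------------------------------------------------------------------
# Result tables


def records_to_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    rows = [r.as_row() for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def histograms_to_frame(histograms: Iterable[RatioHistogram]) -> pd.DataFrame:
    rows = []
    for h in histograms:
        for left, right, count in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            rows.append(
                {
                    "stratum": h.stratum,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows, columns=HISTOGRAM_COLUMNS)


def write_results(
    single_records: Sequence[MorphometryRecord],
    cluster_records: Sequence[MorphometryRecord],
    histograms: Sequence[RatioHistogram],
    out_dir: str | os.PathLike,
    basename: str = "results",
) -> dict[str, Path]:
    """Write the four result sections as CSV files plus one XLSX workbook.

    Sections: single cells, clusters, their combination, and the ratio
    histograms. CSV output is deterministic (byte-identical for identical
    inputs); the workbook carries the same tables in sheets named exactly
    ``single_cells``, ``clusters``, ``combined``, ``histograms``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    singles = records_to_frame(single_records)
    clusters = records_to_frame(cluster_records)
    nonempty = [f for f in (singles, clusters) if len(f)]
    combined = (
        pd.concat(nonempty, ignore_index=True) if nonempty else singles.copy()
    )
    hist = histograms_to_frame(histograms)
    tables = {
        "single_cells": singles,
        "clusters": clusters,
        "combined": combined,
        "histograms": hist,
    }
    paths: dict[str, Path] = {}
    for name, frame in tables.items():
        p = out_dir / f"{basename}_{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
        paths[name] = p
    xlsx = out_dir / f"{basename}.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        for name, frame in tables.items():
            frame.to_excel(writer, sheet_name=name, index=False)
    paths["workbook"] = xlsx
    return paths


def read_results(out_dir: str | os.PathLike, basename: str = "results") -> dict:
    out_dir = Path(out_dir)
    return {
        name: pd.read_csv(out_dir / f"{basename}_{name}.csv")
        for name in ("single_cells", "clusters", "combined", "histograms")
    }


# ---------------------------------------------------------------------------
# Overlays, previews, crops


def _as_uint8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    top = img.max()
    if top <= 0:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.clip(img / top * 255.0, 0, 255).astype(np.uint8)


def render_overlay(
    channel_set: ChannelSet,
    components: Sequence[GliaComponent],
    classes: Sequence[str],
    outline_radius_px: int = 1,
) -> np.ndarray:
    """RGB array with soma outlines and skeletons tinted by activation class
    (activated red, intermediate green, non-activated blue)."""
    if len(components) != len(classes):
        raise ValueError("components and classes must have the same length")
    base = _as_uint8(channel_set.glia_marker.pixels)
    rgb = np.stack([base, base, base], axis=-1)
    se = disk(max(int(outline_radius_px), 1))
    for comp, label in zip(components, classes):
        color = CLASS_COLORS[label]
        outline = comp.soma_mask & ~erosion(comp.soma_mask, se)
        paint = outline.copy()
        if comp.skeleton is not None:
            paint |= comp.skeleton
        sl = comp.slices
        region = rgb[sl]
        region[paint] = color
    return rgb


def write_overlay(
    channel_set: ChannelSet,
    components: Sequence[GliaComponent],
    classes: Sequence[str],
    path: str | os.PathLike,
) -> Path:
    rgb = render_overlay(channel_set, components, classes)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path


def downscale_preview(image: CalibratedImage, factor: float = 0.1) -> CalibratedImage:
    """Mean-resampled preview; dimensions scale by ``factor``, pixel size by
    ``1/factor``. Used for quick-look images at 10% scale."""
    if not (0 < factor < 1):
        raise ValueError(f"preview factor must lie in (0, 1), got {factor}")
    px = np.asarray(image.pixels, dtype=float)
    inv = 1.0 / factor
    if np.isclose(inv, round(inv)) and all(
        s % round(inv) == 0 for s in px.shape
    ):
        small = downscale_local_mean(px, (int(round(inv)),) * 2)
    else:
        out_shape = tuple(max(int(round(s * factor)), 1) for s in px.shape)
        small = resize(px, out_shape, order=1, anti_aliasing=True, preserve_range=True)
    return image.with_pixels(small, pixel_size_um=image.pixel_size_um / factor)


def write_preview(image: CalibratedImage, path: str | os.PathLike, factor: float = 0.1) -> Path:
    small = downscale_preview(image, factor)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, _as_uint8(small.pixels))
    return path


def crop_bounds(
    mask: np.ndarray, pad_px: int, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Padded bounding box of a mask, clipped at the image border."""
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0 = max(int(rows[0]) - pad_px, 0)
    r1 = min(int(rows[-1]) + pad_px + 1, shape[0])
    c0 = max(int(cols[0]) - pad_px, 0)
    c1 = min(int(cols[-1]) + pad_px + 1, shape[1])
    return r0, r1, c0, c1
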