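"""Glia mask, soma and nucleus segmentation for fluorescence and DAB images.

The binarization follows a hysteresis scheme: a *weak* threshold (Otsu by
default) unioned with Sobel-derived edge pixels is morphologically closed,
and only 8-connected structures that also contain at least one pixel above
a *strong* threshold survive. Somata are recovered by partial topological
thinning, opening with a disk wider than any process, and dilating the
survivors back; nuclei come from an Otsu threshold split by a
distance-transform watershed. Every step is deterministic.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import closing, dilation, disk, opening, thin
from skimage.segmentation import watershed

from .datatypes import CalibratedImage, GliaComponent, NucleusMap

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


def _disk_px(radius_um: float, pixel_size_um: float) -> np.ndarray:
    return disk(max(int(round(radius_um / pixel_size_um)), 1))


def chromogen_to_signal(image: CalibratedImage) -> CalibratedImage:
    """Invert a dark-on-bright chromogen (DAB) image so stain is high-valued.

    Integer images invert against the dtype maximum (255 / 65535), floats
    against the image maximum, making the operation an involution on its own
    output. Rejects fluorescence inputs: silently inverting them would
    corrupt every downstream threshold.
    """
    if image.modality != "chromogen":
        raise ValueError(
            "chromogen_to_signal expects a chromogen image; got modality "
            f"{image.modality!r}"
        )
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer):
        top = np.iinfo(px.dtype).max
    else:
        top = float(px.max())
    inverted = top - px
    return image.with_pixels(inverted, role="glia_marker")


class HysteresisParts(NamedTuple):
    mask: np.ndarray
    weak_closed: np.ndarray  # closed union of weak-threshold and edge pixels
    strong: np.ndarray
    weak_threshold: float
    strong_threshold: float


def glia_thresholds(
    pixels: np.ndarray,
    strong_fraction: Optional[float] = None,
    weak_fraction: Optional[float] = None,
    strong_blend: float = 0.5,
) -> tuple[float, float]:
    """Weak/strong intensity thresholds for the hysteresis binarization.

    By default the weak threshold is the Otsu level of the channel and the
    strong one sits ``strong_blend`` of the way from there to the image
    maximum — robust to staining-intensity differences across batches. When
    ``weak_fraction``/``strong_fraction`` are given they are interpreted as
    quantiles of the positive (foreground-candidate) intensities instead.
    """
    px = np.asarray(pixels, dtype=float)
    if strong_fraction is not None or weak_fraction is not None:
        if strong_fraction is None or weak_fraction is None:
            raise ValueError("give both weak_fraction and strong_fraction or neither")
        if not (0 < weak_fraction <= strong_fraction <= 1):
            raise ValueError(
                "threshold fractions out of order: need 0 < weak <= strong <= 1"
            )
        candidates = px[px > 0]
        if candidates.size == 0:
            return np.inf, np.inf
        weak_t = float(np.quantile(candidates, weak_fraction))
        strong_t = float(np.quantile(candidates, strong_fraction))
        return weak_t, strong_t
    if px.max() == px.min():
        return np.inf, np.inf
    weak_t = float(threshold_otsu(px))
    strong_t = weak_t + strong_blend * (float(px.max()) - weak_t)
    return weak_t, strong_t


def binarize_glia(
    image: CalibratedImage,
    strong_fraction: Optional[float] = None,
    weak_fraction: Optional[float] = None,
    closing_radius_um: float = 1.0,
    strong_blend: float = 0.5,
    edge_floor: float = 0.5,
    return_parts: bool = False,
):
    """Hysteresis binarization of the glia-marker channel.

    The output is the union of weak-threshold and edge pixels, closed with a
    disk of ``closing_radius_um``, restricted to 8-connected components that
    contain at least one strong-threshold pixel. Edge pixels (Sobel gradient
    above its own Otsu level) are only admitted where the intensity exceeds
    ``edge_floor`` times the weak threshold, which keeps the one-pixel
    gradient halo outside real structures from inflating the mask while
    still recovering faint thin processes.

    An all-zero or constant image yields an empty mask (not an error).
    """
    px = np.asarray(image.pixels, dtype=float)
    weak_t, strong_t = glia_thresholds(
        px, strong_fraction, weak_fraction, strong_blend
    )
    empty = np.zeros(px.shape, dtype=bool)
    if not np.isfinite(weak_t):
        parts = HysteresisParts(empty, empty.copy(), empty.copy(), weak_t, strong_t)
        return parts if return_parts else parts.mask
    weak = px >= weak_t
    strong = px >= strong_t
    grad = sobel(px)
    if grad.max() > grad.min():
        edge = grad > threshold_otsu(grad)
        edge &= px >= edge_floor * weak_t
    else:
        edge = empty
    weak_closed = closing(weak | edge, _disk_px(closing_radius_um, image.pixel_size_um))
    labels, n = ndi.label(weak_closed, structure=_STRUCT8)
    if n == 0:
        parts = HysteresisParts(empty, weak_closed, strong, weak_t, strong_t)
        return parts if return_parts else parts.mask
    seeded = np.unique(labels[strong & weak_closed])
    seeded = seeded[seeded > 0]
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    mask = keep[labels]
    parts = HysteresisParts(mask, weak_closed, strong, weak_t, strong_t)
    return parts if return_parts else parts.mask


def clean_mask(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 10.0,
    max_hole_um2: float = 5.0,
) -> np.ndarray:
    """Delete structures smaller than ``min_area_um2``, then fill enclosed
    holes of area <= ``max_hole_um2``. Never increases the component count."""
    if min_area_um2 < 0 or max_hole_um2 < 0:
        raise ValueError("area parameters must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    px_area = float(pixel_size_um) ** 2
    out = mask.copy()
    # remove small structures
    labels, n = ndi.label(out, structure=_STRUCT8)
    if n:
        sizes = np.bincount(labels.ravel())
        small = sizes * px_area < min_area_um2
        small[0] = False
        out[small[labels]] = False
    # fill small holes (background components not touching the border,
    # 4-connected complement of the 8-connected foreground)
    holes, n_h = ndi.label(~out, structure=_STRUCT4)
    if n_h:
        border_labels = np.unique(
            np.concatenate(
                [holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]
            )
        )
        sizes = np.bincount(holes.ravel())
        fill = sizes * px_area <= max_hole_um2
        fill[border_labels] = False
        fill[0] = False
        out[fill[holes]] = True
    return out


def _neighbor_groups(patch: np.ndarray) -> int:
    """Number of 8-connected groups among the set neighbours of the center
    of a 3x3 boolean patch, the center excluded."""
    p = patch.copy()
    p[1, 1] = False
    if not p.any():
        return 0
    lab, n = ndi.label(p, structure=_STRUCT8)
    return n


def separate_bridges(mask: np.ndarray, pixel_size_um: float, min_area_um2: float = 10.0) -> np.ndarray:
    """Delete single-pixel bridges between objects.

    A set pixel is removed when deleting it splits its 8-connected component
    into two or more parts, each at least the small-structure minimum
    (``min_area_um2``). Afterwards no such articulation pixel remains; the
    operation never merges components and is idempotent on bridge-free masks.
    """
    mask = np.asarray(mask, dtype=bool)
    min_px = min_area_um2 / float(pixel_size_um) ** 2
    out = np.pad(mask, 1)  # pad so 3x3 windows are always in-bounds
    while True:
        labels, n = ndi.label(out, structure=_STRUCT8)
        if n == 0:
            break
        objects = ndi.find_objects(labels)
        # Articulation pixels must have their set neighbours in >= 2 locally
        # disconnected groups, which requires >= 2 background 4-neighbours —
        # a cheap vectorized pre-filter before the exact per-pixel check.
        bg4 = (
            (~out[:-2, 1:-1]).astype(np.uint8)
            + ~out[2:, 1:-1]
            + ~out[1:-1, :-2]
            + ~out[1:-1, 2:]
        )
        nb8 = (
            out[:-2, :-2].astype(np.uint8)
            + out[:-2, 1:-1]
            + out[:-2, 2:]
            + out[1:-1, :-2]
            + out[1:-1, 2:]
            + out[2:, :-2]
            + out[2:, 1:-1]
            + out[2:, 2:]
        )
        cand = out[1:-1, 1:-1] & (bg4 >= 2) & (nb8 >= 2)
        # among valid articulation pixels prefer the one with the fewest
        # neighbours — a genuine one-pixel bridge has two — so block corners
        # adjacent to a bridge are not chewed off instead of it
        best = None
        for r, c in np.argwhere(cand) + 1:
            patch = out[r - 1 : r + 2, c - 1 : c + 2]
            if _neighbor_groups(patch) < 2:
                continue
            lab = labels[r, c]
            sl = objects[lab - 1]
            sub = labels[sl] == lab
            sub[r - sl[0].start, c - sl[1].start] = False
            sub_lab, n_parts = ndi.label(sub, structure=_STRUCT8)
            if n_parts < 2:
                continue
            sizes = np.bincount(sub_lab.ravel())[1:]
            if np.all(sizes >= min_px):
                key = int(nb8[r - 1, c - 1])
                if best is None or key < best[0]:
                    best = (key, r, c)
        if best is None:
            break
        out[best[1], best[2]] = False  # labels are stale; rescan
    return out[1:-1, 1:-1]


def extract_somata(
    mask: np.ndarray,
    pixel_size_um: float,
    thinning_iters: int = 3,
    opening_radius_um: float = 1.75,
    dilation_radius_um: float = 1.5,
) -> np.ndarray:
    """Soma regions: partial thinning, opening, dilation back, clipped to the
    mask. Structures strictly thinner than the opening disk vanish, so only
    the thicker cell parts — the somata — survive."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    thinned = thin(mask, max_num_iter=thinning_iters) if thinning_iters > 0 else mask
    opened = opening(thinned, _disk_px(opening_radius_um, pixel_size_um))
    if not opened.any():
        return opened
    soma = dilation(opened, _disk_px(dilation_radius_um, pixel_size_um)) & mask
    return soma


def _region_centroids(labels: np.ndarray) -> np.ndarray:
    """Per-label centers of mass, snapped to the nearest pixel of their own
    region when the raw center falls outside it (concave regions)."""
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return np.empty((0, 2))
    coms = ndi.center_of_mass(labels > 0, labels, ids)
    centroids = []
    for lab, (r, c) in zip(ids, coms):
        ri, ci = int(round(r)), int(round(c))
        if (
            0 <= ri < labels.shape[0]
            and 0 <= ci < labels.shape[1]
            and labels[ri, ci] == lab
        ):
            centroids.append((float(r), float(c)))
            continue
        pts = np.argwhere(labels == lab)
        d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2
        centroids.append(tuple(pts[int(np.argmin(d2))].astype(float)))
    return np.asarray(centroids)


def detect_nuclei(
    nucleus_image: CalibratedImage,
    min_nucleus_area_um2: float = 5.0,
    threshold_quantile: Optional[float] = None,
    min_separation_um: float = 1.0,
) -> NucleusMap:
    """Label nuclei in the DAPI channel and build the nucleus position matrix.

    Threshold (Otsu, or a quantile of positive intensities when
    ``threshold_quantile`` is given), fill holes, drop sub-minimum specks,
    then split touching nuclei with a distance-transform watershed whose
    seeds are distance maxima at least ``min_separation_um`` apart. A blank
    channel yields an empty map.
    """
    px = np.asarray(nucleus_image.pixels, dtype=float)
    shape = px.shape
    if px.max() == px.min():
        return NucleusMap(np.zeros(shape, dtype=np.int32), np.empty((0, 2)))
    if threshold_quantile is not None:
        pos = px[px > 0]
        thr = float(np.quantile(pos, threshold_quantile)) if pos.size else np.inf
    else:
        thr = float(threshold_otsu(px))
    mask = px >= thr
    mask = ndi.binary_fill_holes(mask)
    px_area = nucleus_image.pixel_size_um ** 2
    labels0, n0 = ndi.label(mask, structure=_STRUCT8)
    if n0 == 0:
        return NucleusMap(np.zeros(shape, dtype=np.int32), np.empty((0, 2)))
    sizes = np.bincount(labels0.ravel())
    small = sizes * px_area < min_nucleus_area_um2
    small[0] = False
    mask[small[labels0]] = False
    if not mask.any():
        return NucleusMap(np.zeros(shape, dtype=np.int32), np.empty((0, 2)))
    distance = ndi.distance_transform_edt(mask)
    sep_px = max(int(round(min_separation_um / nucleus_image.pixel_size_um)), 1)
    comp_labels, _ = ndi.label(mask, structure=_STRUCT8)
    peaks = peak_local_max(
        distance, min_distance=sep_px, labels=comp_labels, exclude_border=False
    )
    markers = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # guarantee at least one seed per component
    seeded = set(np.unique(comp_labels[markers > 0]))
    next_id = len(peaks) + 1
    for lab in np.unique(comp_labels[comp_labels > 0]):
        if lab in seeded:
            continue
        sub = np.where(comp_labels == lab, distance, -1.0)
        r, c = np.unravel_index(int(np.argmax(sub)), shape)
        markers[r, c] = next_id
        next_id += 1
    labels = watershed(-distance, markers, mask=mask, connectivity=2)
    # relabel sequentially for a stable centroid ordering
    ids = np.unique(labels[labels > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    labels = remap[labels]
    return NucleusMap(labels, _region_centroids(labels))


def soma_surrogate_nuclei(soma_mask: np.ndarray) -> NucleusMap:
    """Nucleus surrogate for chromogen mode: one 'nucleus' per 8-connected
    soma region, located at its centroid."""
    labels, _ = ndi.label(np.asarray(soma_mask, bool), structure=_STRUCT8)
    return NucleusMap(labels.astype(np.int32), _region_centroids(labels))


def assign_components(
    glia_mask: np.ndarray,
    soma_mask: np.ndarray,
    nuclei: Optional[NucleusMap],
    mode: str = "fluorescence",
) -> list[GliaComponent]:
    """Overlap glia components with the nucleus matrix and sort them.

    Each 8-connected component of ``glia_mask`` is annotated with the number
    of nucleus centroids falling on it: zero-nucleus components (stray
    process fragments from cells in other layers) are discarded, one nucleus
    makes a single cell, two or more a cluster. In chromogen mode, where no
    nucleus channel exists, soma-region centroids stand in for nuclei.
    """
    glia_mask = np.asarray(glia_mask, bool)
    soma_mask = np.asarray(soma_mask, bool)
    if mode == "fluorescence":
        if nuclei is None:
            raise ValueError("fluorescence mode requires a nucleus map")
    elif mode == "chromogen":
        if nuclei is None:
            nuclei = soma_surrogate_nuclei(soma_mask)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels, n = ndi.label(glia_mask, structure=_STRUCT8)
    if n == 0 or len(nuclei) == 0:
        return []
    counts = np.zeros(n + 1, dtype=int)
    points: dict[int, list] = {}
    for r, c in nuclei.centroids:
        ri = int(np.clip(round(r), 0, glia_mask.shape[0] - 1))
        ci = int(np.clip(round(c), 0, glia_mask.shape[1] - 1))
        lab = int(labels[ri, ci])
        if lab > 0:
            counts[lab] += 1
            points.setdefault(lab, []).append((r, c))
    components: list[GliaComponent] = []
    objects = ndi.find_objects(labels)
    next_id = 1
    for lab in range(1, n + 1):
        if counts[lab] == 0:
            continue
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        bbox = (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop)
        components.append(
            GliaComponent(
                id=next_id,
                bbox=bbox,
                mask=sub,
                soma_mask=soma_mask[sl] & sub,
                nucleus_count=int(counts[lab]),
                nucleus_points=np.asarray(points[lab]),
            )
        )
        next_id += 1
    return components
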