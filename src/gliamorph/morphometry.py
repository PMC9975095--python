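"""Per-object morphometric and intensity parameters.

Eleven parameters are computed for every glia object: percent fill, soma
(cell-body) area, total process length, the morphology ratio
(process length / soma area, the activation scale: the smaller the ratio
the more activated the cell), number of cells, total cell area, CD68 sum
intensity, endpoint and branch-point counts of the process skeleton, span
ratio and perimeter. Physical outputs carry both pixel and µm columns.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .datatypes import CalibratedImage, ChannelSet, GliaComponent, MorphometryRecord

_SQRT2 = float(np.sqrt(2.0))
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Number of set 8-neighbours of each pixel of a boolean grid."""
    s = np.asarray(skeleton, bool)
    p = np.pad(s, 1).astype(np.uint8)
    return (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
    )


def count_endpoints(skeleton: np.ndarray) -> int:
    """Skeleton pixels with at most one skeleton 8-neighbour (an isolated
    pixel counts as one endpoint)."""
    s = np.asarray(skeleton, bool)
    if not s.any():
        return 0
    return int(np.count_nonzero(s & (neighbor_counts(s) <= 1)))


def count_branchpoints(skeleton: np.ndarray) -> int:
    """Junction count: pixels with >= 3 skeleton neighbours, 8-adjacent
    candidates merged into a single junction."""
    s = np.asarray(skeleton, bool)
    if not s.any():
        return 0
    cand = s & (neighbor_counts(s) >= 3)
    if not cand.any():
        return 0
    _, n = ndi.label(cand, structure=np.ones((3, 3), bool))
    return int(n)


def endpoint_mask(skeleton: np.ndarray) -> np.ndarray:
    s = np.asarray(skeleton, bool)
    return s & (neighbor_counts(s) <= 1)


def process_length(skeleton: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Link-weighted skeleton length: orthogonal neighbour links count 1,
    diagonal links sqrt(2) (each link once), times the pixel size."""
    s = np.asarray(skeleton, bool)
    if not s.any():
        return 0.0
    orth = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(
        s[:-1, :] & s[1:, :]
    )
    diag = np.count_nonzero(s[:-1, :-1] & s[1:, 1:]) + np.count_nonzero(
        s[:-1, 1:] & s[1:, :-1]
    )
    return float((orth + diag * _SQRT2) * pixel_size_um)


def prune_spurs(skeleton: np.ndarray, min_spur_px: int = 6) -> np.ndarray:
    """Remove side twigs shorter than ``min_spur_px`` that hang off a
    junction; free ends of genuine paths are left alone."""
    s = np.asarray(skeleton, bool).copy()
    if min_spur_px <= 1 or not s.any():
        return s
    changed = True
    while changed:
        changed = False
        nb = neighbor_counts(s)
        ends = np.argwhere(s & (nb <= 1))
        for r, c in ends:
            if not s[r, c]:
                continue
            path = [(int(r), int(c))]
            prev = None
            cur = (int(r), int(c))
            hit_junction = False
            while len(path) < min_spur_px:
                nxt = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _RING
                    if 0 <= cur[0] + dr < s.shape[0]
                    and 0 <= cur[1] + dc < s.shape[1]
                    and s[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nxt) == 0:
                    break
                if len(nxt) > 1 or nb[nxt[0]] >= 3:
                    hit_junction = True
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            if hit_junction and len(path) < min_spur_px:
                for p in path:
                    s[p] = False
                changed = True
    return s


def skeletonize_processes(
    component: GliaComponent,
    min_spur_px: int = 6,
    near_soma_px: int = 3,
    min_fragment_px: int = 8,
) -> np.ndarray:
    """Topological thinning of the process region (mask minus soma), pruned
    of short spurs; the result is stored on the component. An amoeboid cell
    with no process region yields an empty skeleton.

    Subtracting the soma leaves thin crescents of cell-body pixels hugging
    the soma boundary; their skeleton arcs are artifacts, so skeleton pixels
    closer than ``near_soma_px`` to the soma are removed and leftover
    fragments shorter than ``min_fragment_px`` discarded — structures below
    roughly 2 µm are under the skeletonization resolution anyway.
    """
    region = component.mask & ~component.soma_mask
    skel = skeletonize(region) if region.any() else region.copy()
    if skel.any() and component.soma_mask.any():
        dist = ndi.distance_transform_edt(~component.soma_mask)
        skel &= dist >= near_soma_px
    if skel.any() and min_fragment_px > 1:
        lab, n = ndi.label(skel, structure=np.ones((3, 3), bool))
        if n:
            sizes = np.bincount(lab.ravel())
            small = sizes < min_fragment_px
            small[0] = False
            skel[small[lab]] = False
    skel = prune_spurs(skel, min_spur_px)
    component.skeleton = skel
    return skel


def percent_fill(mask: np.ndarray) -> float:
    """Object pixel count over its axis-aligned bounding-box pixel count,
    in (0, 1]. Compact (activated) cells fill their box; ramified cells
    leave it mostly empty."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("percent_fill of an empty mask is undefined")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    box = (rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1)
    return float(mask.sum() / box)


def span_ratio(mask: np.ndarray, degenerate_cap: float = 1e6) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (>= 1).

    Collinear (degenerate) masks return ``degenerate_cap``; a single-pixel
    mask is an error.
    """
    pts = np.argwhere(np.asarray(mask, bool)).astype(float)
    if len(pts) < 2:
        raise ValueError("span_ratio needs a mask of at least 2 pixels")
    d = pts - pts.mean(axis=0)
    cov = d.T @ d / len(pts)
    eigs = np.linalg.eigvalsh(cov)
    lo, hi = float(eigs[0]), float(eigs[1])
    if lo <= 1e-12:
        return float(degenerate_cap)
    return float(np.sqrt(hi / lo))


def perimeter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Outer-contour length by Moore boundary tracing, counting orthogonal
    steps as 1 and diagonal steps as sqrt(2), times pixel size.

    Follows the outer boundary only (holes are not traversed). A
    single-pixel mask is scored as a unit square (perimeter 4).
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("perimeter of an empty mask is undefined")
    if m.sum() == 1:
        return float(4.0 * pixel_size_um)
    p = np.pad(m, 1)
    start = tuple(int(v) for v in np.argwhere(p)[0])  # row-major: on boundary
    # Moore-neighbour tracing; state = (boundary pixel, backtrack bg pixel);
    # the walk terminates when a state repeats (one full tour of the contour).
    b = start
    prev = (start[0], start[1] - 1)  # west of the first pixel is background
    seen: dict = {}
    length = 0.0
    while (b, prev) not in seen:
        seen[(b, prev)] = length
        d0 = _RING.index((prev[0] - b[0], prev[1] - b[1]))
        nxt = None
        for k in range(1, 9):
            idx = (d0 + k) % 8
            cand = (b[0] + _RING[idx][0], b[1] + _RING[idx][1])
            if p[cand]:
                last_idx = (d0 + k - 1) % 8
                prev = (b[0] + _RING[last_idx][0], b[1] + _RING[last_idx][1])
                nxt = cand
                break
        if nxt is None:  # pragma: no cover - excluded by the size-1 guard
            break
        length += _SQRT2 if (nxt[0] != b[0] and nxt[1] != b[1]) else 1.0
        b = nxt
    # subtract any lead-in steps taken before entering the closed contour
    return float((length - seen[(b, prev)]) * pixel_size_um)


def marker_sum_intensity(mask: np.ndarray, marker: CalibratedImage | np.ndarray) -> float:
    """Exact sum of marker intensities over the mask pixels, no
    normalization (the CD68 parameter)."""
    pixels = marker.pixels if isinstance(marker, CalibratedImage) else np.asarray(marker)
    mask = np.asarray(mask, bool)
    if pixels.shape != mask.shape:
        raise ValueError(
            f"marker shape {pixels.shape} does not match mask shape {mask.shape}"
        )
    return float(pixels[mask].sum())


def measure(
    component: GliaComponent,
    channels: Optional[ChannelSet],
    pixel_size_um: float,
    min_spur_px: int = 6,
    span_cap: float = 1e6,
    soma_exclusion_px: int = 5,
) -> MorphometryRecord:
    """Assemble the full per-object record.

    The reported endpoint count excludes skeleton endpoints within
    ``soma_exclusion_px`` (Chebyshev) of the soma, so that it counts process
    *tips* rather than the cut where a process meets its cell body; the
    reported process length adds, for each such root end, its gap to the
    soma boundary (the process physically continues to the cell body — the
    gap is an artifact of subtracting the soma before skeletonizing). A
    zero soma area flags the record degenerate and leaves the morphology
    ratio missing.
    """
    if component.skeleton is None:
        skeletonize_processes(component, min_spur_px)
    skel = component.skeleton
    px = float(pixel_size_um)
    px_area = px * px

    cell_area_px = int(component.mask.sum())
    soma_area_px = int(component.soma_mask.sum())
    length_px = process_length(skel, 1.0)
    soma_area_um2 = soma_area_px * px_area

    ends = endpoint_mask(skel)
    if component.soma_mask.any() and ends.any():
        near_soma = ndi.binary_dilation(
            component.soma_mask,
            np.ones((2 * soma_exclusion_px + 1,) * 2, bool),
        )
        root_ends = ends & near_soma
        if root_ends.any():
            gap = ndi.distance_transform_edt(~component.soma_mask)
            length_px += float(gap[root_ends].sum())
        ends = ends & ~near_soma
    n_endpoints = int(ends.sum())
    length_um = length_px * px

    degenerate_soma = soma_area_px == 0
    ratio = None if degenerate_soma else length_um / soma_area_um2

    try:
        span = span_ratio(component.mask, span_cap)
    except ValueError:
        span = span_cap
    degenerate_span = span >= span_cap

    perim_px = perimeter(component.mask, 1.0)

    cd68 = None
    if channels is not None and channels.activation_marker is not None:
        sl = component.slices
        cd68 = marker_sum_intensity(
            component.mask, channels.activation_marker.pixels[sl]
        )

    return MorphometryRecord(
        object_id=component.id,
        n_cells=component.nucleus_count,
        is_cluster=component.is_cluster,
        cell_area_px=cell_area_px,
        cell_area_um2=cell_area_px * px_area,
        soma_area_px=soma_area_px,
        soma_area_um2=soma_area_um2,
        process_length_px=length_px,
        process_length_um=length_um,
        morphology_ratio=ratio,
        percent_fill=percent_fill(component.mask),
        perimeter_px=perim_px,
        perimeter_um=perim_px * px,
        n_endpoints=n_endpoints,
        n_branchpoints=count_branchpoints(skel),
        span_ratio=span,
        cd68_sum_intensity=cd68,
        degenerate_soma=degenerate_soma,
        degenerate_span=degenerate_span,
    )
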