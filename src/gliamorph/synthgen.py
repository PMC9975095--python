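"""Synthetic microglia scenes with exact ground truth.

Cells are built generatively: a soma disk plus persistent-random-walk
processes (optionally branching) whose polylines live in continuous µm
coordinates, so every truth quantity — soma area, total process length,
tip and branch counts — is analytic on the constructed geometry rather
than read off rendered pixels. Scenes are rendered as three fluorescence
channels (glia marker, nucleus, CD68) with optional Gaussian PSF blur and
additive noise, or re-rendered chromogen-style (dark stain on a bright
transmitted-light background). Identical seeds give identical scenes.

Process polylines of one cell are kept mutually separated by a margin
larger than the closing element of the segmentation stage, so that on
noise-free scenes the rendered geometry survives the pipeline without
topological surprises; this is a property of the generator's geometry, not
a tuning of the analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk

from .datatypes import CalibratedImage, ChannelSet

DEFAULT_PIXEL_SIZE_UM = 0.334  # plausible 20x high-content sampling


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative parameters of one morphological phenotype.

    Ranges are inclusive; lengths and radii in µm. The three bundled
    phenotypes emulate the surveillance-to-phagocytic continuum: ramified
    cells have small somata with many long thin processes and low CD68,
    amoeboid cells a large bare soma with high CD68 ("completely amoeboid
    ... no processes extending from the cell body"), intermediates sit in
    between — monotone in soma size and CD68 across the scale.
    """

    label: str
    soma_radius_um: tuple[float, float]
    n_processes: tuple[int, int]
    process_length_um: tuple[float, float]
    branch_prob_per_step: float
    process_width_um: float
    cd68_level: float


RAMIFIED = PhenotypeSpec("ramified", (3.0, 4.5), (4, 6), (18.0, 30.0), 0.010, 1.0, 0.15)
INTERMEDIATE = PhenotypeSpec(
    "intermediate", (4.5, 6.0), (2, 4), (10.0, 16.0), 0.004, 1.2, 0.45
)
AMOEBOID = PhenotypeSpec("amoeboid", (6.0, 8.0), (0, 0), (0.0, 0.0), 0.0, 1.5, 0.90)
PHENOTYPES = {p.label: p for p in (RAMIFIED, INTERMEDIATE, AMOEBOID)}

# geometry safety margins (µm); see module docstring
_SEPARATION_UM = 4.5
_BRANCH_ZONE_UM = 6.0
_BRANCH_SEPARATION_UM = 4.0
_STEP_FRACTION = 1.0  # walk step = pixel size


@dataclass
class CellGeometry:
    """One constructed cell in local µm coordinates (origin = soma center)."""

    phenotype: str
    soma_radius_um: float
    polylines: list  # list of (n, 2) float arrays, µm, local coords
    n_branchpoints: int
    process_width_um: float
    cd68_level: float
    center_um: Optional[np.ndarray] = None  # set at placement, scene coords

    @property
    def process_length_um(self) -> float:
        total = 0.0
        for pl in self.polylines:
            if len(pl) > 1:
                total += float(np.linalg.norm(np.diff(pl, axis=0), axis=1).sum())
        return total

    @property
    def n_endpoints(self) -> int:
        # one free tip per polyline (trunks and branches alike)
        return len(self.polylines)

    @property
    def soma_area_um2(self) -> float:
        return float(np.pi * self.soma_radius_um**2)

    @property
    def extent_um(self) -> float:
        ext = self.soma_radius_um
        for pl in self.polylines:
            if len(pl):
                ext = max(ext, float(np.linalg.norm(pl, axis=1).max()))
        return ext + self.process_width_um


def _walk(
    start: np.ndarray,
    theta0: float,
    length: float,
    step: float,
    rng: np.random.Generator,
    drift_sigma: float = 0.03,
) -> np.ndarray:
    n = max(int(round(length / step)), 1)
    dtheta = rng.normal(0.0, drift_sigma, size=n)
    theta = theta0 + np.cumsum(dtheta)
    steps = np.stack([np.cos(theta), np.sin(theta)], axis=1) * step
    return start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).min())


def generate_cell(
    spec: PhenotypeSpec,
    rng: np.random.Generator,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    max_branches_per_process: int = 2,
) -> CellGeometry:
    """Construct one cell: soma disk plus separated random-walk processes.

    Processes start just inside the soma boundary in evenly spaced
    directions (small angular jitter) and walk outward with persistent
    small-angle drift; branches split off at 25-40 degrees. A candidate
    polyline is resampled when it dips back into the soma or comes closer
    than the separation margin to an existing polyline, so the constructed
    geometry is guaranteed non-self-intersecting.
    """
    r_soma = float(rng.uniform(*spec.soma_radius_um))
    n_proc = int(rng.integers(spec.n_processes[0], spec.n_processes[1] + 1))
    step = pixel_size_um * _STEP_FRACTION
    polylines: list[np.ndarray] = []
    accepted_pts: list[np.ndarray] = []
    n_branch = 0
    if n_proc > 0:
        phi0 = rng.uniform(0, 2 * np.pi)
        jitter = np.deg2rad(8.0)
        for k in range(n_proc):
            base = phi0 + 2 * np.pi * k / n_proc
            length = float(rng.uniform(*spec.process_length_um))
            placed = None
            for _ in range(6):
                theta = base + rng.uniform(-jitter, jitter)
                start = (r_soma - pixel_size_um) * np.array(
                    [np.cos(theta), np.sin(theta)]
                )
                pl = _walk(start, theta, length, step, rng)
                radii = np.linalg.norm(pl[1:], axis=1)
                if np.any(radii < r_soma - 0.3):
                    continue
                # separation is only meaningful beyond the soma vicinity:
                # trunks legitimately converge toward the cell body
                def _far(pts):
                    return pts[np.linalg.norm(pts, axis=1) > r_soma + 1.5]

                others = (
                    np.vstack([_far(p) for p in accepted_pts])
                    if accepted_pts
                    else np.empty((0, 2))
                )
                if _min_dist(_far(pl), others) < _SEPARATION_UM:
                    continue
                placed = pl
                break
            if placed is None:
                continue
            polylines.append(placed)
            accepted_pts.append(placed)
            # branches off this trunk
            if spec.branch_prob_per_step > 0:
                n_steps = len(placed)
                draws = rng.random(n_steps)
                cand_idx = [
                    i
                    for i in range(n_steps)
                    if draws[i] < spec.branch_prob_per_step
                    and (i * step) > 4.0
                    and (length - i * step) > 10.0
                ]
                branches_here = 0
                for i in cand_idx:
                    if branches_here >= max_branches_per_process:
                        break
                    junction = placed[i]
                    tangent = placed[min(i + 1, n_steps - 1)] - placed[i - 1]
                    theta_p = float(np.arctan2(tangent[1], tangent[0]))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    theta_b = theta_p + sign * np.deg2rad(rng.uniform(30, 45))
                    b_len = float(rng.uniform(9.0, max(10.0, 0.6 * (length - i * step))))
                    bpl = None
                    for _ in range(4):
                        cand = _walk(junction, theta_b, b_len, step, rng)
                        radii = np.linalg.norm(cand[1:], axis=1)
                        if np.any(radii < r_soma - 0.3):
                            continue
                        far_b = cand[
                            np.linalg.norm(cand - junction, axis=1) > _BRANCH_ZONE_UM
                        ]
                        far_p = placed[
                            np.linalg.norm(placed - junction, axis=1) > _BRANCH_ZONE_UM
                        ]
                        if _min_dist(far_b, far_p) < _BRANCH_SEPARATION_UM:
                            continue
                        rest = [p for p in accepted_pts if p is not placed]
                        others = np.vstack(rest) if rest else np.empty((0, 2))
                        if _min_dist(cand, others) < _SEPARATION_UM:
                            continue
                        bpl = cand
                        break
                    if bpl is not None:
                        polylines.append(bpl)
                        accepted_pts.append(bpl)
                        n_branch += 1
                        branches_here += 1
    return CellGeometry(
        phenotype=spec.label,
        soma_radius_um=r_soma,
        polylines=polylines,
        n_branchpoints=n_branch,
        process_width_um=spec.process_width_um,
        cd68_level=spec.cd68_level,
    )


@dataclass
class ClusterSpec:
    """A forced-contact chain of cells rendered as one touching object."""

    n_cells: int
    phenotype: str = "amoeboid"
    spacing_factor: float = 0.75  # of the summed soma radii: overlap

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("a cluster needs at least 2 cells")


@dataclass
class SceneGroundTruth:
    """Per-cell truth (from geometry, not pixels) plus scene metadata."""

    cells: list  # list of dicts
    pixel_size_um: float
    image_shape: tuple[int, int]
    noise_sigma: float
    blur_sigma_um: float
    seed: Optional[int] = None
    clusters: list = field(default_factory=list)  # lists of cell ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells)

    def to_json(self, path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SceneGroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["image_shape"] = tuple(doc["image_shape"])
        return cls(**doc)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _render_cell_mask(
    cell: CellGeometry, shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean patch mask of one placed cell (soma disk + ribbons) and the
    full-frame slices it occupies."""
    center_px = cell.center_um / pixel_size_um
    ext_px = int(np.ceil(cell.extent_um / pixel_size_um)) + 3
    r0 = max(int(np.floor(center_px[0])) - ext_px, 0)
    c0 = max(int(np.floor(center_px[1])) - ext_px, 0)
    r1 = min(int(np.ceil(center_px[0])) + ext_px + 1, shape[0])
    c1 = min(int(np.ceil(center_px[1])) + ext_px + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    patch = (
        (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2
    ) <= (cell.soma_radius_um / pixel_size_um) ** 2
    if cell.polylines:
        lines = np.zeros_like(patch)
        for pl in cell.polylines:
            pts = np.round((pl + cell.center_um) / pixel_size_um).astype(int)
            pts[:, 0] -= r0
            pts[:, 1] -= c0
            ok = (
                (pts[:, 0] >= 0)
                & (pts[:, 0] < patch.shape[0])
                & (pts[:, 1] >= 0)
                & (pts[:, 1] < patch.shape[1])
            )
            lines[pts[ok, 0], pts[ok, 1]] = True
        half_w = max(int(round(0.5 * cell.process_width_um / pixel_size_um)), 1)
        patch |= dilation(lines, disk(half_w))
    return patch, (slice(r0, r1), slice(c0, c1))


def _disk_mask(
    center_px: np.ndarray, radius_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, tuple[slice, slice]]:
    ext = int(np.ceil(radius_px)) + 2
    r0 = max(int(np.floor(center_px[0])) - ext, 0)
    c0 = max(int(np.floor(center_px[1])) - ext, 0)
    r1 = min(int(np.ceil(center_px[0])) + ext + 1, shape[0])
    c1 = min(int(np.ceil(center_px[1])) + ext + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    patch = ((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2) <= radius_px**2
    return patch, (slice(r0, r1), slice(c0, c1))


def generate_scene(
    n_per_phenotype: dict[str, int],
    clusters: Sequence[ClusterSpec] = (),
    image_shape: Optional[tuple[int, int]] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    blur_sigma_um: float = 0.4,
    noise_sigma: float = 4.0,
    nucleus_radius_um: float = 2.5,
    min_separation_um: float = 3.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ChannelSet, SceneGroundTruth]:
    """Render a field of cells with ground truth.

    Isolated cells are placed with non-overlapping footprints; each
    ``ClusterSpec`` adds a chain of touching cells rendered as one
    connected object. One nucleus blob sits at every soma center. Raises
    when the requested density cannot be placed in the given image.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cells: list[CellGeometry] = []
    for label in ("ramified", "intermediate", "amoeboid"):  # fixed draw order
        for _ in range(int(n_per_phenotype.get(label, 0))):
            cells.append(generate_cell(PHENOTYPES[label], rng, pixel_size_um))

    cluster_groups: list[list[CellGeometry]] = []
    for cs in clusters:
        spec = PHENOTYPES[cs.phenotype]
        group = [generate_cell(spec, rng, pixel_size_um) for _ in range(cs.n_cells)]
        cluster_groups.append(group)

    # footprint radii: for clusters, a chain laid out around its own origin
    placements: list[dict] = [{"kind": "cell", "obj": c, "ext": c.extent_um} for c in cells]
    for group in cluster_groups:
        offsets = _chain_offsets(group, rng, nucleus_radius_um)
        ext = max(
            float(np.linalg.norm(off) + c.extent_um)
            for off, c in zip(offsets, group)
        )
        placements.append(
            {"kind": "cluster", "obj": group, "offsets": offsets, "ext": ext}
        )

    if image_shape is None:
        side_um = max(
            float(np.sqrt(sum((3.2 * p["ext"]) ** 2 for p in placements))),
            4.2 * max((p["ext"] for p in placements), default=10.0),
        )
        side = int(np.ceil(side_um / pixel_size_um))
        image_shape = (side, side)

    shape = tuple(image_shape)
    h_um = shape[0] * pixel_size_um
    w_um = shape[1] * pixel_size_um
    centers: list[np.ndarray] = []
    exts: list[float] = []
    order = sorted(range(len(placements)), key=lambda i: -placements[i]["ext"])
    positions: dict[int, np.ndarray] = {}
    for idx in order:
        ext = placements[idx]["ext"]
        if 2 * ext >= min(h_um, w_um):
            raise ValueError("image too small for the requested objects")
        ok = False
        for _ in range(2000):
            pos = np.array(
                [
                    rng.uniform(ext + 1, h_um - ext - 1),
                    rng.uniform(ext + 1, w_um - ext - 1),
                ]
            )
            if all(
                np.linalg.norm(pos - c) >= ext + e + min_separation_um
                for c, e in zip(centers, exts)
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                "requested cell density impossible at this image size"
            )
        centers.append(pos)
        exts.append(ext)
        positions[idx] = pos

    glia = np.zeros(shape, dtype=float)
    nucleus = np.zeros(shape, dtype=float)
    cd68 = np.zeros(shape, dtype=float)
    truth_cells: list[dict] = []
    truth_clusters: list[list[int]] = []
    cell_id = 0

    def _add_cell(cell: CellGeometry, center_um: np.ndarray, cluster_id):
        nonlocal cell_id
        cell.center_um = center_um
        mask, sl = _render_cell_mask(cell, shape, pixel_size_um)
        amp = rng.uniform(160.0, 210.0)
        np.maximum(glia[sl], amp * mask, out=glia[sl])
        center_px = center_um / pixel_size_um
        nuc, nsl = _disk_mask(center_px, nucleus_radius_um / pixel_size_um, shape)
        amp_n = rng.uniform(150.0, 200.0)
        np.maximum(nucleus[nsl], amp_n * nuc, out=nucleus[nsl])
        soma, ssl = _disk_mask(center_px, cell.soma_radius_um / pixel_size_um, shape)
        amp_c = cell.cd68_level * rng.uniform(0.85, 1.15) * 200.0
        np.maximum(cd68[ssl], amp_c * soma, out=cd68[ssl])
        truth_cells.append(
            {
                "cell_id": cell_id,
                "phenotype": cell.phenotype,
                "soma_center_px": [float(center_px[0]), float(center_px[1])],
                "soma_radius_um": cell.soma_radius_um,
                "soma_area_um2": cell.soma_area_um2,
                "process_length_um": cell.process_length_um,
                "n_processes": len(cell.polylines),
                "n_endpoints": cell.n_endpoints,
                "n_branchpoints": cell.n_branchpoints,
                "nucleus_center_px": [float(center_px[0]), float(center_px[1])],
                "cd68_total": float(amp_c * cell.soma_area_um2 / pixel_size_um**2),
                "cluster_id": cluster_id,
            }
        )
        cell_id += 1

    for idx in range(len(placements)):  # original order for stable ids
        p = placements[idx]
        pos = positions[idx]
        if p["kind"] == "cell":
            _add_cell(p["obj"], pos, None)
        else:
            ids = []
            for off, cell in zip(p["offsets"], p["obj"]):
                ids.append(cell_id)
                _add_cell(cell, pos + off, len(truth_clusters))
            truth_clusters.append(ids)

    if blur_sigma_um > 0:
        sig = blur_sigma_um / pixel_size_um
        for arr in (glia, nucleus, cd68):
            ndi.gaussian_filter(arr, sig, output=arr)
    if noise_sigma > 0:
        for arr in (glia, nucleus, cd68):
            arr += rng.normal(0.0, noise_sigma, size=shape)
            np.clip(arr, 0.0, None, out=arr)

    channels = ChannelSet(
        glia_marker=CalibratedImage(glia, pixel_size_um, "fluorescence", "glia_marker"),
        nucleus=CalibratedImage(nucleus, pixel_size_um, "fluorescence", "nucleus"),
        activation_marker=CalibratedImage(
            cd68, pixel_size_um, "fluorescence", "activation_marker"
        ),
    )
    truth = SceneGroundTruth(
        cells=truth_cells,
        pixel_size_um=pixel_size_um,
        image_shape=shape,
        noise_sigma=noise_sigma,
        blur_sigma_um=blur_sigma_um,
        seed=seed,
        clusters=truth_clusters,
    )
    return channels, truth


def _chain_offsets(
    group: Sequence[CellGeometry],
    rng: np.random.Generator,
    nucleus_radius_um: float,
) -> list[np.ndarray]:
    """Offsets placing a cluster's somata in a gently curving, overlapping
    chain whose nuclei stay disjoint."""
    min_center_gap = 2 * nucleus_radius_um + 1.0
    for _ in range(50):
        theta = rng.uniform(0, 2 * np.pi)
        offsets = [np.zeros(2)]
        ok = True
        for prev, cur in zip(group[:-1], group[1:]):
            spacing = max(
                0.75 * (prev.soma_radius_um + cur.soma_radius_um), min_center_gap
            )
            theta += rng.uniform(-0.35, 0.35)
            offsets.append(
                offsets[-1] + spacing * np.array([np.cos(theta), np.sin(theta)])
            )
        pts = np.asarray(offsets)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < min_center_gap:
            ok = False
        if ok:
            centroid = pts.mean(axis=0)
            return [p - centroid for p in pts]
    raise ValueError("could not lay out a non-self-colliding cluster chain")


def render_chromogen(
    channels: ChannelSet,
    background: float = 250.0,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> CalibratedImage:
    """DAB-style re-rendering: bright background minus the glia signal.

    With zero noise the inversion performed by the chromogen analysis mode
    recovers the fluorescent glia channel exactly (the background carries
    the image maximum). No nucleus channel exists in this modality.
    """
    glia = channels.glia_marker.pixels.astype(float)
    if glia.max() >= background:
        raise ValueError("background level must exceed the glia signal maximum")
    img = background - glia
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = np.clip(img + rng.normal(0, noise_sigma, glia.shape), 0, None)
    return CalibratedImage(
        img, channels.pixel_size_um, modality="chromogen", role="transmitted"
    )


def reference_scene(
    seed: int = 0, n_per_phenotype: int = 30, noise_free: bool = False
) -> tuple[ChannelSet, SceneGroundTruth]:
    """The bundled calibration scene: equal numbers of each phenotype."""
    kwargs = dict(blur_sigma_um=0.0, noise_sigma=0.0) if noise_free else {}
    return generate_scene(
        {"ramified": n_per_phenotype, "intermediate": n_per_phenotype, "amoeboid": n_per_phenotype},
        seed=seed,
        **kwargs,
    )


def write_scene(
    channels: ChannelSet,
    truth: SceneGroundTruth,
    out_dir,
    basename: str = "scene",
) -> dict[str, Path]:
    """Write the channels as TIFF and the truth as JSON + CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ch in (
        ("glia", channels.glia_marker),
        ("nucleus", channels.nucleus),
        ("cd68", channels.activation_marker),
    ):
        if ch is None:
            continue
        p = out_dir / f"{basename}_{name}.tif"
        tifffile.imwrite(p, ch.pixels.astype(np.float32))
        paths[name] = p
    jp = out_dir / f"{basename}_truth.json"
    truth.to_json(jp)
    paths["truth_json"] = jp
    cp = out_dir / f"{basename}_truth.csv"
    truth.to_frame().to_csv(cp, index=False, lineterminator="\n")
    paths["truth_csv"] = cp
    return paths
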