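"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* images are 2D numpy arrays indexed ``(row, col)``, 0-based, with masks
  interpreted at pixel centers;
* connectivity is 8-neighbour throughout;
* physical sizes are micrometres, converted through ``pixel_size_um``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MODALITIES = ("fluorescence", "chromogen")
ROLES = ("glia_marker", "nucleus", "activation_marker", "transmitted")


@dataclass
class CalibratedImage:
    """A 2D intensity grid with physical pixel size and channel semantics.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities. Never rescaled by the
        package: marker sum intensities depend on raw values.
    pixel_size_um
        Side length of one pixel in micrometres (> 0).
    modality
        ``"fluorescence"`` (bright signal on dark background) or
        ``"chromogen"`` (dark stain on bright transmitted-light background).
    role
        One of ``glia_marker``, ``nucleus``, ``activation_marker``,
        ``transmitted``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    modality: str = "fluorescence"
    role: str = "glia_marker"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("image intensities must be finite")
        if float(self.pixels.min()) < 0:
            raise ValueError("image intensities must be non-negative")
        if not (float(self.pixel_size_um) > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    def with_pixels(self, pixels: np.ndarray, **overrides) -> "CalibratedImage":
        kw = dict(
            pixel_size_um=self.pixel_size_um, modality=self.modality, role=self.role
        )
        kw.update(overrides)
        return CalibratedImage(pixels, **kw)


@dataclass
class ChannelSet:
    """The channels of one field: glia marker plus optional nucleus / CD68."""

    glia_marker: CalibratedImage
    nucleus: Optional[CalibratedImage] = None
    activation_marker: Optional[CalibratedImage] = None

    def __post_init__(self) -> None:
        ref = self.glia_marker
        for ch in (self.nucleus, self.activation_marker):
            if ch is None:
                continue
            if ch.shape != ref.shape:
                raise ValueError("all channels must share identical dimensions")
            if not np.isclose(ch.pixel_size_um, ref.pixel_size_um):
                raise ValueError("all channels must share the same pixel size")

    @property
    def pixel_size_um(self) -> float:
        return self.glia_marker.pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.glia_marker.shape


@dataclass
class RoiPolygon:
    """A simple polygon in 0-based (row, col) pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


@dataclass
class NucleusMap:
    """Labelled nuclei and their centroid matrix.

    ``labels`` is an integer grid (0 = background); ``centroids`` is the
    nucleus position matrix, one (row, col) point per label, ordered by
    label id, each guaranteed to lie inside its own region.
    """

    labels: np.ndarray
    centroids: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        n_labels = len(np.unique(self.labels[self.labels > 0]))
        if n_labels != len(self.centroids):
            raise ValueError("centroid count must equal number of labels")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class GliaComponent:
    """One 8-connected glia object with its soma, skeleton and nuclei.

    Masks are stored cropped to ``bbox = (r0, r1, c0, c1)`` (half-open) in
    the full-image frame, so large scenes stay cheap; ``nucleus_points``
    are absolute (row, col) centroids of the nuclei covered by the object.
    """

    id: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray  # bool, cropped to bbox
    soma_mask: np.ndarray
    nucleus_count: int
    skeleton: Optional[np.ndarray] = None
    nucleus_points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("mask shape must match bbox extent")
        if self.soma_mask.shape != self.mask.shape:
            raise ValueError("soma mask must share the mask's shape")
        if np.any(self.soma_mask & ~self.mask):
            raise ValueError("soma mask must be a subset of the object mask")
        if self.skeleton is not None and np.any(
            np.asarray(self.skeleton, bool) & ~self.mask
        ):
            raise ValueError("skeleton must be a subset of the object mask")
        if self.nucleus_count < 1:
            raise ValueError("a retained component must cover >= 1 nucleus")

    @property
    def is_cluster(self) -> bool:
        return self.nucleus_count >= 2

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.bbox
        return slice(r0, r1), slice(c0, c1)


#: Column order of result tables; fixed so writers are byte-reproducible.
RECORD_COLUMNS = [
    "object_id",
    "is_cluster",
    "n_cells",
    "percent_fill",
    "soma_area_px",
    "soma_area_um2",
    "process_length_px",
    "process_length_um",
    "morphology_ratio",
    "cell_area_px",
    "cell_area_um2",
    "cd68_sum_intensity",
    "n_endpoints",
    "n_branchpoints",
    "span_ratio",
    "perimeter_px",
    "perimeter_um",
    "degenerate_soma",
    "degenerate_span",
]


@dataclass
class MorphometryRecord:
    """The eleven per-object parameters plus bookkeeping flags.

    ``morphology_ratio`` is process length (µm) divided by soma area (µm²);
    it is ``None`` (missing) when the soma area is zero, in which case the
    record is flagged degenerate.
    """

    object_id: int
    n_cells: int
    is_cluster: bool
    cell_area_px: int
    cell_area_um2: float
    soma_area_px: int
    soma_area_um2: float
    process_length_px: float
    process_length_um: float
    morphology_ratio: Optional[float]
    percent_fill: float
    perimeter_px: float
    perimeter_um: float
    n_endpoints: int
    n_branchpoints: int
    span_ratio: float
    cd68_sum_intensity: Optional[float] = None
    degenerate_soma: bool = False
    degenerate_span: bool = False

    def as_row(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: d[k] for k in RECORD_COLUMNS}


@dataclass
class ActivationThresholds:
    """Morphology-ratio cutoffs of the three-way activation scale.

    Ratios below ``t_low`` are *activated*, ratios in ``[t_low, t_high]``
    *intermediate*, above ``t_high`` *non_activated*.
    """

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (self.t_low < self.t_high):
            raise ValueError("thresholds must satisfy t_low < t_high")


CLASS_LABELS = ("activated", "intermediate", "non_activated")
CLASS_COLORS = {  # RGB used by overlays and crops
    "activated": (255, 0, 0),
    "intermediate": (0, 255, 0),
    "non_activated": (0, 0, 255),
}


@dataclass
class RatioHistogram:
    """Counts of morphology ratios for one stratum of objects."""

    stratum: str  # "single_cells" | "clusters" | "all"
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")


@dataclass
class CellSample:
    """A seeded random sample of single cells for manual validation."""

    component_ids: list[int]
    seed: int
    pad_px: int
    classes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.component_ids)) != len(self.component_ids):
            raise ValueError("sampled ids must be distinct")


@dataclass
class AgreementReport:
    """Tally of manual-vs-automated detection and scoring agreement."""

    n_evaluated: int
    n_true_positive: int
    n_false_positive: int
    n_false_negative_detection: int
    n_score_mismatch: int
    spearman_rho: Optional[float]
    spearman_ci: Optional[tuple[float, float]] = None
    unmatched_ids: Sequence = ()


@dataclass
class FractionatorParams:
    """Optical-fractionator sampling fractions and raw count."""

    ssf: float
    asf: float
    hsf: float
    q_counted: int

    def __post_init__(self) -> None:
        for name in ("ssf", "asf", "hsf"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.q_counted < 0:
            raise ValueError("q_counted must be >= 0")
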