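"""End-to-end analysis and validation runs.

``analyze_channels`` drives the in-memory pipeline (binarize → clean →
separate → somata → nuclei → components → measure → classify → filter →
histograms); ``run_analyze`` / ``run_validate`` wrap it with file input,
result/overlay/preview/crop output and a machine-readable provenance
record. Validation runs share every image-processing step with analysis
and add seeded sampling plus optional agreement scoring.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify as cls, image_io, morphometry, segmentation, validation
from .datatypes import (
    ActivationThresholds,
    CalibratedImage,
    ChannelSet,
    GliaComponent,
    MorphometryRecord,
    NucleusMap,
    RatioHistogram,
)

log = logging.getLogger("gliamorph")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its effective default.

    All radii/areas are physical (µm, µm²) and converted internally by the
    pixel size; thresholds ``t_low``/``t_high`` are morphology-ratio units
    (µm per µm²).
    """

    pixel_size_um: float = 1.0
    modality: str = "fluorescence"
    # binarization
    strong_fraction: Optional[float] = None
    weak_fraction: Optional[float] = None
    strong_blend: float = 0.5
    closing_radius_um: float = 1.0
    edge_floor: float = 0.5
    # mask corrections
    min_area_um2: float = 10.0
    max_hole_um2: float = 5.0
    # soma extraction
    thinning_iters: int = 3
    opening_radius_um: float = 1.75
    dilation_radius_um: float = 1.5
    # nuclei
    min_nucleus_area_um2: float = 5.0
    nucleus_threshold_quantile: Optional[float] = None
    nucleus_min_separation_um: float = 1.0
    # morphometry
    min_spur_px: int = 6
    span_cap: float = 1e6
    soma_exclusion_px: int = 5
    # classification / reporting
    t_low: float = cls.DEFAULT_THRESHOLDS.t_low
    t_high: float = cls.DEFAULT_THRESHOLDS.t_high
    max_cluster_cells: int = 15
    bin_edges: Optional[list] = None

    @property
    def thresholds(self) -> ActivationThresholds:
        return ActivationThresholds(self.t_low, self.t_high)

    def histogram_edges(self) -> np.ndarray:
        if self.bin_edges is not None:
            return np.asarray(self.bin_edges, dtype=float)
        return cls.DEFAULT_BIN_EDGES


@dataclass
class AnalysisResult:
    channels: ChannelSet
    glia_mask: np.ndarray
    soma_mask: np.ndarray
    nuclei: Optional[NucleusMap]
    components: list[GliaComponent]
    records: list[MorphometryRecord]
    classes: list[str]
    records_filtered: list[MorphometryRecord]
    n_cluster_filtered: int
    histograms: list[RatioHistogram]
    stage_counts: dict

    @property
    def single_records(self) -> list[MorphometryRecord]:
        return [r for r in self.records_filtered if not r.is_cluster]

    @property
    def cluster_records(self) -> list[MorphometryRecord]:
        return [r for r in self.records_filtered if r.is_cluster]

    def class_of(self, object_id: int) -> str:
        for rec, c in zip(self.records, self.classes):
            if rec.object_id == object_id:
                return c
        raise KeyError(object_id)


def analyze_channels(
    channels: ChannelSet, config: PipelineConfig
) -> AnalysisResult:
    """Run the full in-memory pipeline on a channel set.

    In chromogen mode the transmitted-light image is inverted first and
    soma centroids substitute for nuclei; fluorescence mode requires a
    nucleus channel.
    """
    cfg = config
    stage_counts: dict = {}
    glia_img = channels.glia_marker
    if cfg.modality == "chromogen":
        if glia_img.modality != "chromogen":
            glia_img = CalibratedImage(
                glia_img.pixels, glia_img.pixel_size_um, "chromogen", "transmitted"
            )
        glia_img = segmentation.chromogen_to_signal(glia_img)
    elif channels.nucleus is None:
        raise ValueError(
            "fluorescence mode requires a nucleus channel for cluster sorting"
        )

    raw_mask = segmentation.binarize_glia(
        glia_img,
        strong_fraction=cfg.strong_fraction,
        weak_fraction=cfg.weak_fraction,
        closing_radius_um=cfg.closing_radius_um,
        strong_blend=cfg.strong_blend,
        edge_floor=cfg.edge_floor,
    )
    stage_counts["binarize_px"] = int(raw_mask.sum())
    cleaned = segmentation.clean_mask(
        raw_mask, cfg.pixel_size_um, cfg.min_area_um2, cfg.max_hole_um2
    )
    separated = segmentation.separate_bridges(
        cleaned, cfg.pixel_size_um, cfg.min_area_um2
    )
    soma_mask = segmentation.extract_somata(
        separated,
        cfg.pixel_size_um,
        thinning_iters=cfg.thinning_iters,
        opening_radius_um=cfg.opening_radius_um,
        dilation_radius_um=cfg.dilation_radius_um,
    )
    if cfg.modality == "fluorescence":
        nuclei = segmentation.detect_nuclei(
            channels.nucleus,
            min_nucleus_area_um2=cfg.min_nucleus_area_um2,
            threshold_quantile=cfg.nucleus_threshold_quantile,
            min_separation_um=cfg.nucleus_min_separation_um,
        )
    else:
        nuclei = segmentation.soma_surrogate_nuclei(soma_mask)
    stage_counts["nuclei"] = len(nuclei)
    components = segmentation.assign_components(
        separated, soma_mask, nuclei, mode=cfg.modality
    )
    stage_counts["components"] = len(components)
    stage_counts["single_cells"] = sum(1 for c in components if not c.is_cluster)
    stage_counts["clusters"] = sum(1 for c in components if c.is_cluster)

    records = []
    for comp in components:
        morphometry.skeletonize_processes(comp, cfg.min_spur_px)
        records.append(
            morphometry.measure(
                comp,
                channels,
                cfg.pixel_size_um,
                min_spur_px=cfg.min_spur_px,
                span_cap=cfg.span_cap,
                soma_exclusion_px=cfg.soma_exclusion_px,
            )
        )
    classes = cls.classify_all(records, cfg.thresholds)
    filtered, n_removed = cls.filter_clusters(records, cfg.max_cluster_cells)
    stage_counts["cluster_filtered"] = n_removed
    histograms = cls.build_histograms(filtered, cfg.histogram_edges())
    if not components:
        log.warning("no glia components detected; results will be empty")
    return AnalysisResult(
        channels=channels,
        glia_mask=separated,
        soma_mask=soma_mask,
        nuclei=nuclei if cfg.modality == "fluorescence" else nuclei,
        components=components,
        records=records,
        classes=classes,
        records_filtered=filtered,
        n_cluster_filtered=n_removed,
        histograms=histograms,
        stage_counts=stage_counts,
    )


# ---------------------------------------------------------------------------
# File-based runs


@dataclass
class RunConfig:
    """File-level configuration of one CLI run."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    glia_path: Optional[str] = None
    nucleus_path: Optional[str] = None
    activation_path: Optional[str] = None
    roi_path: Optional[str] = None
    out_dir: str = "gliamorph_out"
    image_id: str = "image"
    # validation mode
    sample_n: Optional[int] = None
    seed: Optional[int] = None
    crop_pad_px: int = 20
    manual_scores_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        pipe = PipelineConfig(**doc.pop("pipeline", {}))
        return cls(pipeline=pipe, **doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_channels(config: RunConfig) -> ChannelSet:
    cfg = config.pipeline
    if config.glia_path is None:
        raise ValueError("a glia-marker (or transmitted) image path is required")
    role = "transmitted" if cfg.modality == "chromogen" else "glia_marker"
    glia = image_io.read_channel(
        config.glia_path, cfg.pixel_size_um, cfg.modality, role
    )
    nucleus = None
    activation = None
    if config.nucleus_path:
        nucleus = image_io.read_channel(
            config.nucleus_path, cfg.pixel_size_um, cfg.modality, "nucleus"
        )
    if config.activation_path:
        activation = image_io.read_channel(
            config.activation_path, cfg.pixel_size_um, cfg.modality, "activation_marker"
        )
    channels = ChannelSet(glia, nucleus, activation)
    if config.roi_path:
        rois = image_io.read_rois(config.roi_path)
        roi_mask = np.zeros(channels.shape, dtype=bool)
        for roi in rois:
            roi_mask |= image_io.rasterize_roi(roi, channels.shape)
        for ch in (channels.glia_marker, channels.nucleus, channels.activation_marker):
            if ch is not None:
                px = ch.pixels.copy()
                if cfg.modality == "chromogen":
                    px[~roi_mask] = px.max()  # outside ROI looks like background
                else:
                    px[~roi_mask] = 0
                ch.pixels = px
    return channels


def _write_provenance(config: RunConfig, result: AnalysisResult, out: Path, extra=None):
    doc = {
        "gliamorph_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stage_counts": result.stage_counts,
    }
    if extra:
        doc.update(extra)
    with open(out / "run_provenance.json", "w") as fh:
        json.dump(doc, fh, indent=1, default=str)


def run_analyze(
    config: RunConfig, channels: Optional[ChannelSet] = None
) -> AnalysisResult:
    """Analysis mode: full pipeline plus tables, overlay and previews."""
    if channels is None:
        channels = load_channels(config)
    result = analyze_channels(channels, config.pipeline)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_io.write_results(
        result.single_records,
        result.cluster_records,
        result.histograms,
        out,
        basename=f"{config.image_id}_results",
    )
    image_io.write_overlay(
        channels, result.components, result.classes, out / f"{config.image_id}_overlay.png"
    )
    image_io.write_preview(
        channels.glia_marker, out / f"{config.image_id}_preview.png"
    )
    _write_provenance(config, result, out)
    for stage, count in result.stage_counts.items():
        log.info("%s: %s", stage, count)
    return result


def run_validate(
    config: RunConfig, channels: Optional[ChannelSet] = None
) -> tuple[AnalysisResult, validation.CellSample, Optional[validation.AgreementReport]]:
    """Validation mode: analysis preprocessing, seeded sampling, crops, and
    (when manual scores are supplied) the agreement report."""
    if config.seed is None or config.sample_n is None:
        raise ValueError("validation mode requires both a seed and a sample size")
    if channels is None:
        channels = load_channels(config)
    result = analyze_channels(channels, config.pipeline)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    class_by_id = {
        r.object_id: c for r, c in zip(result.records, result.classes)
    }
    sample = validation.sample_cells(
        result.components,
        config.sample_n,
        config.seed,
        pad_px=config.crop_pad_px,
        classes=class_by_id,
    )
    validation.export_crops(
        sample, channels, result.components, out / "crops", image_id=config.image_id
    )
    validation.write_sample_manifest(
        sample, result.records, out / f"{config.image_id}_sample_manifest.csv"
    )
    report = None
    if config.manual_scores_path:
        manual = pd.read_csv(config.manual_scores_path)
        report = validation.score_agreement(manual, result.records, class_by_id)
        frame = pd.DataFrame([dataclasses.asdict(report)])
        frame.to_csv(
            out / f"{config.image_id}_agreement.csv", index=False, lineterminator="\n"
        )
    _write_provenance(
        config, result, out, extra={"sample_ids": sample.component_ids}
    )
    return result, sample, report
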