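"""Validation mode: seeded cell sampling, crop export, agreement scoring.

A pre-defined number of detected single cells is drawn uniformly without
replacement with a named, seedable generator; each sampled cell is exported
as a padded crop with its soma outline and skeleton tinted by activation
class (activated red, intermediate green, non-activated blue) so an
investigator can score it on the 4-point manual scale. Replicate manual
scores are averaged (rounded half up), mapped onto the automated classes,
and tallied against the automated results.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.morphology import disk, erosion

from .classify import manual_score_to_class, spearman_correlation
from .datatypes import (
    AgreementReport,
    CLASS_COLORS,
    CellSample,
    ChannelSet,
    GliaComponent,
    MorphometryRecord,
)
from .image_io import _as_uint8


def sample_cells(
    components: Sequence[GliaComponent],
    n: int,
    seed: int,
    pad_px: int = 20,
    classes: Optional[dict[int, str]] = None,
) -> CellSample:
    """Uniform, seeded sample of single cells without replacement.

    Requesting more cells than are available returns every single cell;
    identical seeds give identical samples. Zero detected single cells
    yields an empty sample.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    singles = sorted(c.id for c in components if not c.is_cluster)
    if not singles:
        return CellSample(component_ids=[], seed=seed, pad_px=pad_px)
    rng = np.random.default_rng(seed)
    k = min(n, len(singles))
    chosen = rng.choice(np.asarray(singles), size=k, replace=False)
    classes = classes or {}
    return CellSample(
        component_ids=[int(i) for i in chosen],
        seed=seed,
        pad_px=pad_px,
        classes={int(i): classes[int(i)] for i in chosen if int(i) in classes},
    )


def render_crop(
    component: GliaComponent,
    channel_set: ChannelSet,
    class_label: str,
    pad_px: int,
) -> np.ndarray:
    """RGB crop of one cell, class-tinted soma outline + skeleton."""
    shape = channel_set.shape
    r0c, r1c, c0c, c1c = component.bbox
    r0, r1, c0, c1 = (
        max(r0c - pad_px, 0),
        min(r1c + pad_px, shape[0]),
        max(c0c - pad_px, 0),
        min(c1c + pad_px, shape[1]),
    )
    base = _as_uint8(channel_set.glia_marker.pixels[r0:r1, c0:c1])
    rgb = np.stack([base] * 3, axis=-1)
    paint = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    rr = slice(r0c - r0, r0c - r0 + (r1c - r0c))
    cc = slice(c0c - c0, c0c - c0 + (c1c - c0c))
    outline = component.soma_mask & ~erosion(component.soma_mask, disk(1))
    paint[rr, cc] |= outline
    if component.skeleton is not None:
        paint[rr, cc] |= component.skeleton
    rgb[paint] = CLASS_COLORS[class_label]
    return rgb


def export_crops(
    sample: CellSample,
    channel_set: ChannelSet,
    components: Sequence[GliaComponent],
    out_dir: str | os.PathLike,
    image_id: str = "image",
) -> list[Path]:
    """One PNG per sampled cell; filenames encode image id, cell id, class."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create crop directory {out_dir}: {exc}") from exc
    by_id = {c.id: c for c in components}
    paths = []
    for cid in sample.component_ids:
        comp = by_id[cid]
        label = sample.classes.get(cid, "intermediate")
        rgb = render_crop(comp, channel_set, label, sample.pad_px)
        path = out_dir / f"{image_id}_cell{cid:04d}_{label}.png"
        iio.imwrite(path, rgb)
        paths.append(path)
    return paths


def write_sample_manifest(
    sample: CellSample,
    records: Sequence[MorphometryRecord],
    path: str | os.PathLike,
) -> Path:
    by_id = {r.object_id: r for r in records}
    rows = []
    for cid in sample.component_ids:
        rec = by_id.get(cid)
        rows.append(
            {
                "cell_id": cid,
                "class": sample.classes.get(cid, ""),
                "morphology_ratio": "" if rec is None or rec.morphology_ratio is None
                else rec.morphology_ratio,
                "seed": sample.seed,
            }
        )
    frame = pd.DataFrame(rows, columns=["cell_id", "class", "morphology_ratio", "seed"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def score_agreement(
    manual_scores: pd.DataFrame,
    records: Sequence[MorphometryRecord],
    classes: dict[int, str],
) -> AgreementReport:
    """Tally manual 4-point scores (three replicate readings per cell)
    against the automated classification.

    ``manual_scores`` columns: ``cell_id, rep1, rep2, rep3`` and optionally
    ``identified`` (1/0: did the algorithm correctly trace the cell). The
    replicate average is rounded half up, mapped to the 3-class scheme, and
    compared with the automated class; the Spearman correlation between
    rounded score and automated morphology ratio is reported over the true
    positives. Manual ids with no automated record are false-negative
    detections; unmatched ids are listed and excluded with a warning field.
    """
    required = {"cell_id", "rep1", "rep2", "rep3"}
    if not required.issubset(manual_scores.columns):
        raise ValueError(f"manual score table needs columns {sorted(required)}")
    by_id = {r.object_id: r for r in records}
    n_false_negative = 0
    unmatched = []
    n_tp = 0
    n_fp = 0
    n_mismatch = 0
    scores = []
    ratios = []
    for row in manual_scores.itertuples(index=False):
        cid = int(row.cell_id)
        rec = by_id.get(cid)
        if rec is None:
            n_false_negative += 1
            unmatched.append(cid)
            continue
        rounded = round_half_up(np.mean([row.rep1, row.rep2, row.rep3]))
        rounded = int(np.clip(rounded, 1, 4))
        identified = int(getattr(row, "identified", 1))
        if not identified:
            n_fp += 1
            continue
        n_tp += 1
        manual_class = manual_score_to_class(rounded)
        auto_class = classes.get(cid)
        if auto_class is not None and manual_class != auto_class:
            n_mismatch += 1
        scores.append(rounded)
        ratios.append(
            rec.morphology_ratio if rec.morphology_ratio is not None else 0.0
        )
    rho, ci = (None, None)
    if len(scores) >= 3:
        try:
            rho, ci = spearman_correlation(scores, ratios)
        except ValueError:
            rho, ci = None, None
    return AgreementReport(
        n_evaluated=n_tp + n_fp,
        n_true_positive=n_tp,
        n_false_positive=n_fp,
        n_false_negative_detection=n_false_negative,
        n_score_mismatch=n_mismatch,
        spearman_rho=rho,
        spearman_ci=ci,
        unmatched_ids=tuple(unmatched),
    )
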