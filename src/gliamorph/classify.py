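"""Activation classification, cluster filtering and descriptive statistics.

Objects are placed on a continuous activation scale by their morphology
ratio (process length / soma area): the smaller the ratio the more
activated the cell. Two cutoffs split the scale into *activated* /
*intermediate* / *non-activated*. The original cutoffs were never published
numerically, so they are configuration values here, with package defaults
derived by tercile calibration against the bundled synthetic reference
scene (see :func:`calibrate_thresholds`).

Group contrasts are reported descriptively as geometric mean ratios of
log-transformed outcomes and Spearman rank correlations. Repeated-measures
random-effects modelling (animal-level random intercepts, covariate
adjustment) is intentionally out of scope.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import (
    ActivationThresholds,
    CLASS_LABELS,
    MorphometryRecord,
    RatioHistogram,
)

#: Frozen output of ``calibrate_thresholds`` on the reference scene
#: (``synthgen.reference_scene(seed=0)``); override per experiment.
DEFAULT_THRESHOLDS = ActivationThresholds(t_low=0.10, t_high=1.0)

#: Histogram bin edges used when none are configured (morphology-ratio units).
DEFAULT_BIN_EDGES = np.concatenate([[0.0], np.geomspace(0.05, 10.0, 24)])


def _record_ratio(record: MorphometryRecord) -> Optional[float]:
    return record.morphology_ratio


def classify(
    record: MorphometryRecord | float | None,
    thresholds: ActivationThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Three-way activation class of one object.

    ``ratio < t_low`` is activated, ``t_low <= ratio <= t_high``
    intermediate (both boundaries inclusive), larger ratios non-activated.
    Degenerate records with no soma (missing ratio) classify as activated —
    a cell reduced to a body with no measurable processes.
    """
    if not isinstance(thresholds, ActivationThresholds):
        raise ValueError("thresholds must be an ActivationThresholds instance")
    ratio = _record_ratio(record) if isinstance(record, MorphometryRecord) else record
    if ratio is None or not math.isfinite(ratio):
        return "activated" if ratio is None else "non_activated"
    if ratio < thresholds.t_low:
        return "activated"
    if ratio <= thresholds.t_high:
        return "intermediate"
    return "non_activated"


def classify_all(
    records: Sequence[MorphometryRecord],
    thresholds: ActivationThresholds = DEFAULT_THRESHOLDS,
) -> list[str]:
    return [classify(r, thresholds) for r in records]


def class_proportions(labels: Sequence[str]) -> dict[str, float]:
    n = max(len(labels), 1)
    return {lab: sum(1 for x in labels if x == lab) / n for lab in CLASS_LABELS}


def filter_clusters(
    records: Sequence[MorphometryRecord], max_cells: int = 15
) -> tuple[list[MorphometryRecord], int]:
    """Drop cluster records with more than ``max_cells`` cells (single cells
    are always retained). Returns the kept records and the removed count.

    Mirrors the outlier guard applied to cell-body-area and process-length
    models, which were restricted to clusters of 15 cells or fewer.
    """
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    kept = [r for r in records if r.n_cells <= max_cells or not r.is_cluster]
    return kept, len(records) - len(kept)


def build_histograms(
    records: Sequence[MorphometryRecord],
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> list[RatioHistogram]:
    """Morphology-ratio histograms for single cells, clusters, and all.

    Interior edges are half-open (a value exactly on an edge falls in the
    right-hand bin); the last bin is right-inclusive. Ratios outside the
    edge range are clipped into the first/last bin so counts always sum to
    the stratum size; degenerate records count as ratio 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    def ratios(rs):
        return np.asarray(
            [r.morphology_ratio if r.morphology_ratio is not None else 0.0 for r in rs],
            dtype=float,
        )

    strata = {
        "single_cells": [r for r in records if not r.is_cluster],
        "clusters": [r for r in records if r.is_cluster],
        "all": list(records),
    }
    out = []
    for name, rs in strata.items():
        vals = np.clip(ratios(rs), edges[0], edges[-1]) if rs else np.empty(0)
        counts, _ = np.histogram(vals, bins=edges)
        out.append(RatioHistogram(stratum=name, bin_edges=edges, counts=counts))
    return out


def log_shift_transform(values, shift: float = 0.0) -> np.ndarray:
    """Natural log of (value + shift).

    Endpoint counts contain zeros and are shifted by 0.5 before the log;
    the other log-transformed outcomes use shift 0.
    """
    vals = np.asarray(values, dtype=float)
    shifted = vals + shift
    bad = np.nonzero(~(shifted > 0))[0]
    if bad.size:
        raise ValueError(
            f"log transform undefined at index {int(bad[0])}: "
            f"value {vals.flat[bad[0]]} + shift {shift} is not positive"
        )
    return np.log(shifted)


def geometric_mean_ratio(group_a, group_b) -> float:
    """exp(mean log a − mean log b): the fold change between two groups.

    A ratio of 1.5 corresponds to a 50% increase of group A over group B,
    0.5 to a 50% decrease.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("geometric mean ratio requires strictly positive values")
    return float(np.exp(np.mean(np.log(a)) - np.mean(np.log(b))))


def spearman_correlation(
    x, y, confidence: float = 0.95
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Spearman rank correlation (average ranks for ties) with a Fisher-z
    confidence interval. Constant input makes the coefficient undefined and
    returns ``(None, None)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho = float(sps.spearmanr(x, y).statistic)
    n = len(x)
    if abs(rho) >= 1.0 or n <= 3:
        return rho, (rho, rho)
    z = np.arctanh(rho)
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    half = zcrit / math.sqrt(n - 3)
    return rho, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def calibrate_thresholds(
    ratios_by_label: dict[str, Sequence[float]],
    low_q: float = 0.9,
    high_q: float = 0.1,
) -> ActivationThresholds:
    """Derive (t_low, t_high) from labelled reference ratio distributions.

    ``t_low`` is the midpoint between the upper tail (``low_q`` quantile) of
    the amoeboid ratios and the lower tail of the intermediate ratios;
    ``t_high`` the analogous midpoint between intermediate and ramified.
    """
    for key in ("amoeboid", "intermediate", "ramified"):
        if key not in ratios_by_label or len(ratios_by_label[key]) == 0:
            raise ValueError(f"need non-empty ratios for phenotype {key!r}")
    am = np.asarray(ratios_by_label["amoeboid"], float)
    im = np.asarray(ratios_by_label["intermediate"], float)
    ra = np.asarray(ratios_by_label["ramified"], float)
    t_low = 0.5 * (np.quantile(am, low_q) + np.quantile(im, high_q))
    t_high = 0.5 * (np.quantile(im, low_q) + np.quantile(ra, high_q))
    if not t_low < t_high:
        raise ValueError("reference distributions do not separate the classes")
    return ActivationThresholds(float(t_low), float(t_high))


# Mapping of the 4-point manual scale to the automated 3-class scheme,
# used for agreement scoring only: 4 = fully amoeboid/rod (activated),
# 2-3 = intermediate, 1 = ramified (non-activated).
def manual_score_to_class(score: int) -> str:
    score = int(score)
    if score not in (1, 2, 3, 4):
        raise ValueError(f"manual scores are 1-4, got {score}")
    if score == 4:
        return "activated"
    if score == 1:
        return "non_activated"
    return "intermediate"
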