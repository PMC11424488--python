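"""Post-classifier morphology metrics for prostate H&E sections.

Consumes Gleason label rasters (integer maps produced upstream by a
segmentation model) and classified cell tables (x, y, type, Gleason label)
and computes: slide-level primary/secondary Gleason patterns, ISUP grade
group (2014 criteria), continuous Gleason, the Morisita-Horn mixing index
between the primary- and secondary-pattern epithelial populations (Gleason
Morisita), the Tumor-Immune Morisita, and patient-level aggregation.

Morisita-Horn between count vectors x, y over shared quadrats:

    M = 2 * sum(x_i * y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)

with X = sum(x), Y = sum(y); M = 1 for proportionally identical
distributions, 0 for disjoint ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

__all__ = [
    "NO_GLAND",
    "BENIGN",
    "TUMOR_PATTERNS",
    "SlideAssessment",
    "slide_gleason_score",
    "isup_grade_group",
    "continuous_gleason",
    "morisita_horn",
    "gleason_morisita",
    "tumor_immune_morisita",
    "aggregate_patient",
]

NO_GLAND = 0
BENIGN = 1
TUMOR_PATTERNS = (3, 4, 5)


@dataclass
class SlideAssessment:
    """Slide-level morphology summary."""

    primary_pattern: Optional[int] = None
    secondary_pattern: Optional[int] = None
    isup_group: Optional[int] = None
    continuous_gleason: Optional[float] = None
    gleason_morisita: Optional[float] = None
    tumor_immune_morisita: Optional[float] = None
    tumor_area: int = 0
    is_cancer: bool = False


def slide_gleason_score(label_map: np.ndarray,
                        secondary_floor: float = 0.05) -> SlideAssessment:
    """Primary/secondary Gleason pattern from a label raster.

    Tumor patterns are ranked by pixel area; the largest is primary. The
    second-largest becomes secondary only if it covers at least
    ``secondary_floor`` of the tumor area (a trace pattern does not change
    the score), else secondary = primary. A raster without tumor pixels is
    not cancer.
    """
    label_map = np.asarray(label_map)
    areas = {p: int(np.sum(label_map == p)) for p in TUMOR_PATTERNS}
    tumor_area = sum(areas.values())
    if tumor_area == 0:
        return SlideAssessment(is_cancer=False, tumor_area=0)
    ranked = sorted(areas.items(), key=lambda kv: (-kv[1], kv[0]))
    primary = ranked[0][0]
    secondary = primary
    if len(ranked) > 1 and ranked[1][1] >= secondary_floor * tumor_area and ranked[1][1] > 0:
        secondary = ranked[1][0]
    return SlideAssessment(
        primary_pattern=primary,
        secondary_pattern=secondary,
        isup_group=isup_grade_group(primary, secondary),
        continuous_gleason=continuous_gleason(label_map),
        tumor_area=tumor_area,
        is_cancer=True,
    )


def isup_grade_group(primary: int, secondary: int) -> int:
    """ISUP 2014 grade group from primary + secondary Gleason patterns."""
    pair = (primary, secondary)
    total = primary + secondary
    if pair == (3, 3):
        return 1
    if pair == (3, 4):
        return 2
    if pair == (4, 3):
        return 3
    if total == 8:
        return 4
    if total >= 9:
        return 5
    raise ValueError(f"patterns outside the Gleason 3-5 vocabulary: {pair}")


def continuous_gleason(label_map: np.ndarray) -> Optional[float]:
    """Tumor-pixel-area-weighted mean Gleason pattern, in [3, 5].

    Benign and no-gland pixels are excluded; None when no tumor pixels.
    """
    label_map = np.asarray(label_map)
    areas = np.array([np.sum(label_map == p) for p in TUMOR_PATTERNS], dtype=float)
    if areas.sum() == 0:
        return None
    return float(np.dot(TUMOR_PATTERNS, areas) / areas.sum())


def morisita_horn(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Morisita-Horn overlap of two count vectors over shared quadrats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        return None
    num = 2.0 * np.dot(x, y)
    den = (np.dot(x, x) / X**2 + np.dot(y, y) / Y**2) * X * Y
    return float(num / den)


# ---------------------------------------------------------------------------
# quadrat machinery


def _voronoi_labels(points: np.ndarray, all_xy: np.ndarray, seed: int = 0) -> tuple:
    """Assign points to Voronoi quadrats seeded by k-means of all cells.

    k = max(10, ceil(n_cells / 100)); nearest-seed assignment is exactly
    Voronoi cell membership.
    """
    n = len(all_xy)
    if n < 2:
        raise ValueError("need at least 2 cells to seed quadrats")
    k = min(n, max(10, math.ceil(n / 100)))
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(all_xy)
    tree = cKDTree(km.cluster_centers_)
    _, labels = tree.query(points)
    return labels, k


def _grid_labels(points: np.ndarray, all_xy: np.ndarray, n: int = 50) -> tuple:
    """Assign points to an n x n rectangular grid over the tissue bounding box."""
    lo = all_xy.min(axis=0)
    hi = all_xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    ij = np.clip(((points - lo) / span * n).astype(int), 0, n - 1)
    return ij[:, 0] * n + ij[:, 1], n * n


def _quadrat_counts(cells: pd.DataFrame, mask_a, mask_b, mode: str,
                    grid_n: int = 50, seed: int = 0) -> tuple:
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if mode == "voronoi":
        labels, k = _voronoi_labels(xy, xy, seed=seed)
    elif mode == "grid":
        labels, k = _grid_labels(xy, xy, n=grid_n)
    else:
        raise ValueError(f"unknown quadrat mode {mode!r}")
    a = np.bincount(labels[np.asarray(mask_a)], minlength=k)
    b = np.bincount(labels[np.asarray(mask_b)], minlength=k)
    return a, b


def gleason_morisita(cells: pd.DataFrame, assessment: SlideAssessment,
                     mode: str = "voronoi", label_map: Optional[np.ndarray] = None,
                     grid_n: int = 50, seed: int = 0) -> Optional[float]:
    """Morisita-Horn mixing of primary- vs secondary-pattern epithelium.

    Defined as 0 when the primary and secondary patterns coincide (for
    instance a 4 + 4 section). ``mode='voronoi'`` uses k-means-seeded
    Voronoi quadrats over all cells, ``'grid'`` a ``grid_n`` x ``grid_n``
    rectangular grid, and ``'segmentation'`` replaces cell counts with
    per-quadrat pixel areas of the two patterns on ``label_map``.
    """
    if not assessment.is_cancer:
        return None
    if assessment.primary_pattern == assessment.secondary_pattern:
        return 0.0
    if mode == "segmentation":
        if label_map is None:
            raise ValueError("segmentation mode requires a label map")
        return _segmentation_morisita(label_map, assessment.primary_pattern,
                                      assessment.secondary_pattern, grid_n)
    epi = (cells["type"] == "epithelial").to_numpy()
    mask_a = epi & (cells["gleason_label"] == assessment.primary_pattern).to_numpy()
    mask_b = epi & (cells["gleason_label"] == assessment.secondary_pattern).to_numpy()
    a, b = _quadrat_counts(cells, mask_a, mask_b, mode, grid_n=grid_n, seed=seed)
    return morisita_horn(a, b)


def _segmentation_morisita(label_map: np.ndarray, primary: int, secondary: int,
                           grid_n: int) -> Optional[float]:
    h, w = label_map.shape
    rows = np.minimum((np.arange(h) * grid_n) // max(h, 1), grid_n - 1)
    cols = np.minimum((np.arange(w) * grid_n) // max(w, 1), grid_n - 1)
    quad = rows[:, None] * grid_n + cols[None, :]
    a = np.bincount(quad[label_map == primary], minlength=grid_n * grid_n)
    b = np.bincount(quad[label_map == secondary], minlength=grid_n * grid_n)
    return morisita_horn(a, b)


def tumor_immune_morisita(cells: pd.DataFrame, mode: str = "voronoi",
                          grid_n: int = 50, seed: int = 0) -> Optional[float]:
    """Morisita-Horn mixing of tumor-pattern epithelium and immune cells.

    None when the slide has no immune (or no tumor epithelial) cells.
    """
    epi = (cells["type"] == "epithelial").to_numpy()
    tumor = epi & cells["gleason_label"].isin(TUMOR_PATTERNS).to_numpy()
    immune = (cells["type"] == "immune").to_numpy()
    if tumor.sum() == 0 or immune.sum() == 0:
        return None
    a, b = _quadrat_counts(cells, tumor, immune, mode, grid_n=grid_n, seed=seed)
    return morisita_horn(a, b)


# ---------------------------------------------------------------------------
# patient-level aggregation


def aggregate_patient(slides: Sequence[SlideAssessment]) -> dict:
    """Patient-level summary over cancer slides.

    Grade group is the tumor-area-weighted mean of slide grade groups,
    rounded down — a patient is grade group 5 only if every cancer slide is.
    Patient Gleason Morisita is the median across cancer slides (the mean is
    also reported); continuous Gleason is the tumor-area-weighted mean.
    """
    cancer = [s for s in slides if s.is_cancer]
    if not cancer:
        raise ValueError("patient aggregation requires at least one cancer slide")
    w = np.array([s.tumor_area for s in cancer], dtype=float)
    groups = np.array([s.isup_group for s in cancer], dtype=float)
    grade_group = int(np.floor(np.average(groups, weights=w)))
    morisitas = np.array([s.gleason_morisita for s in cancer
                          if s.gleason_morisita is not None], dtype=float)
    cg = np.array([(s.continuous_gleason, s.tumor_area) for s in cancer
                   if s.continuous_gleason is not None], dtype=float)
    return {
        "patient_grade_group": grade_group,
        "patient_gleason_morisita": float(np.median(morisitas)) if len(morisitas) else None,
        "mean_gleason_morisita": float(np.mean(morisitas)) if len(morisitas) else None,
        "patient_continuous_gleason": (
            float(np.average(cg[:, 0], weights=cg[:, 1])) if len(cg) else None
        ),
        "n_cancer_slides": len(cancer),
    }
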