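"""Proximity ligation assay (PLA) image quantification.

Mirrors the standard ImageJ workflow for scoring PLA experiments: threshold
the nuclear (DAPI) channel, keep connected components above a minimum area as
nuclei, threshold the signal channel and keep small components as PLA foci,
assign each focus to the nucleus containing its centroid, and summarize foci
per nucleus with a t-distribution confidence interval. Antibody pairings are
compared with Welch's unequal-variance t-test. Nuclear fluorescence is
quantified as the mean of per-nucleus mean intensities minus a background
level measured on a negative-control line (floored at zero), on the 0-255
8-bit scale.

Size thresholds are expressed in pixels; published workflows often use
calibrated units with the nuclear minimum area roughly an order of magnitude
above the focus minimum, and the defaults here preserve that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "NucleusMask",
    "FocusSet",
    "PlaResult",
    "IntensityResult",
    "segment_nuclei",
    "detect_foci",
    "count_nuclear_foci",
    "summarize_foci",
    "welch_t_test",
    "mean_nuclear_intensity",
    "DEFAULT_NUCLEUS_MIN_AREA",
    "DEFAULT_FOCUS_MIN_AREA",
]

# pixel-area defaults keeping the ~10x nucleus:focus ratio of calibrated workflows
DEFAULT_NUCLEUS_MIN_AREA = 100
DEFAULT_FOCUS_MIN_AREA = 4


@dataclass(frozen=True)
class NucleusMask:
    """Labeled nuclei (positive integer labels) with per-label pixel areas."""

    labels: np.ndarray
    areas: dict[int, int]
    min_area_px: int

    @property
    def n_nuclei(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class FocusSet:
    """Detected PLA foci: labeled regions with centroids."""

    labels: np.ndarray
    centroids: tuple[tuple[float, float], ...]
    areas: tuple[int, ...]
    min_area_px: int

    @property
    def n_foci(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class PlaResult:
    """Per-nucleus foci counts and summary statistics for one pairing."""

    counts: tuple[int, ...]
    n_cells: int
    mean_foci: float
    ci_low: float
    ci_high: float
    confidence: float
    extranuclear: int = 0

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "mean_foci": self.mean_foci,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "confidence": self.confidence,
            "extranuclear": self.extranuclear,
        }


@dataclass(frozen=True)
class IntensityResult:
    """Background-subtracted mean nuclear fluorescence."""

    per_nucleus_means: tuple[float, ...]
    background: float
    mean_intensity: float  # mean of per-nucleus means, before subtraction
    subtracted: float  # floored at 0


def _check_image(image: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be a single-channel 2-D image, got shape {arr.shape}")
    return arr


def _threshold(image: np.ndarray, intensity_threshold: Optional[float]) -> np.ndarray:
    if intensity_threshold is None:
        if image.max() == image.min():
            return np.zeros(image.shape, dtype=bool)  # flat image: nothing above Otsu
        intensity_threshold = threshold_otsu(image)
    return image > intensity_threshold


def segment_nuclei(
    nucleus_image: np.ndarray,
    intensity_threshold: Optional[float] = None,
    min_area_px: int = DEFAULT_NUCLEUS_MIN_AREA,
) -> NucleusMask:
    """Label nuclei as connected components above threshold and minimum area.

    ``intensity_threshold=None`` selects Otsu's threshold. Components below
    ``min_area_px`` are discarded and the remaining labels are renumbered
    contiguously from 1. An empty image yields an empty mask.
    """
    img = _check_image(nucleus_image, "nucleus image")
    if min_area_px < 1:
        raise ValueError(f"min_area_px must be >= 1, got {min_area_px}")
    binary = _threshold(img, intensity_threshold)
    labeled = measure.label(binary, connectivity=2)
    out = np.zeros_like(labeled)
    areas: dict[int, int] = {}
    next_label = 0
    for region in measure.regionprops(labeled):
        if region.area >= min_area_px:
            next_label += 1
            out[labeled == region.label] = next_label
            areas[next_label] = int(region.area)
    return NucleusMask(labels=out, areas=areas, min_area_px=int(min_area_px))


def detect_foci(
    signal_image: np.ndarray,
    intensity_threshold: Optional[float] = None,
    min_area_px: int = DEFAULT_FOCUS_MIN_AREA,
) -> FocusSet:
    """Detect PLA foci as small above-threshold connected components.

    Overlapping foci merge into a single connected component and are counted
    once; this matches binary-mask counting in the standard workflow.
    """
    img = _check_image(signal_image, "signal image")
    if min_area_px < 1:
        raise ValueError(f"min_area_px must be >= 1, got {min_area_px}")
    binary = _threshold(img, intensity_threshold)
    labeled = measure.label(binary, connectivity=2)
    centroids: list[tuple[float, float]] = []
    areas: list[int] = []
    out = np.zeros_like(labeled)
    next_label = 0
    for region in measure.regionprops(labeled):
        if region.area >= min_area_px:
            next_label += 1
            out[labeled == region.label] = next_label
            centroids.append(tuple(region.centroid))
            areas.append(int(region.area))
    return FocusSet(
        labels=out,
        centroids=tuple(centroids),
        areas=tuple(areas),
        min_area_px=int(min_area_px),
    )


def count_nuclear_foci(mask: NucleusMask, foci: FocusSet) -> tuple[dict[int, int], int]:
    """Assign each focus to the nucleus containing its centroid.

    Returns ``(per-nucleus counts keyed by nucleus label, extranuclear count)``.
    Foci whose centroid falls outside every nucleus are counted separately.
    """
    if mask.labels.shape != foci.labels.shape:
        raise ValueError(
            f"mask and foci geometries differ: {mask.labels.shape} vs {foci.labels.shape}"
        )
    counts = {label: 0 for label in mask.areas}
    extranuclear = 0
    for (r, c) in foci.centroids:
        label = int(mask.labels[int(round(r)), int(round(c))])
        if label > 0:
            counts[label] += 1
        else:
            extranuclear += 1
    return counts, extranuclear


def summarize_foci(
    counts: Sequence[int],
    confidence: float = 0.95,
    extranuclear: int = 0,
) -> PlaResult:
    """Mean foci per nucleus with a t-distribution confidence interval."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.rint(arr)):
        raise ValueError("foci counts must be non-negative integers")
    if arr.size < 2:
        raise ValueError("need at least 2 per-nucleus counts for a confidence interval")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    n = arr.size
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n))
    if sem == 0.0:
        lo = hi = mean
    else:
        lo, hi = stats.t.interval(confidence, df=n - 1, loc=mean, scale=sem)
    return PlaResult(
        counts=tuple(int(c) for c in arr),
        n_cells=n,
        mean_foci=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        confidence=confidence,
        extranuclear=int(extranuclear),
    )


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test assuming unequal variances.

    Returns ``(t, Satterthwaite df, two-tailed p)``. When both samples are
    degenerate (zero variance) with equal means the comparison is vacuous and
    ``(0.0, nan, 1.0)`` is returned by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        raise ValueError("both samples have zero variance with different means; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mean_nuclear_intensity(
    mask: NucleusMask,
    signal_image: np.ndarray,
    background_value: float,
) -> IntensityResult:
    """Background-subtracted nuclear fluorescence on the 0-255 scale.

    Each nucleus contributes the mean of the signal pixels under its label;
    the per-image statistic is the unweighted mean of those per-nucleus means
    (not a pixel-pooled mean), minus the background, floored at zero.
    """
    img = _check_image(signal_image, "signal image")
    if img.shape != mask.labels.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape} vs {mask.labels.shape}")
    if background_value < 0:
        raise ValueError("background_value must be >= 0")
    if mask.n_nuclei == 0:
        raise ValueError("mask contains no nuclei; mean nuclear intensity undefined")
    per_label = tuple(
        float(img[mask.labels == label].mean()) for label in sorted(mask.areas)
    )
    overall = float(np.mean(per_label))
    return IntensityResult(
        per_nucleus_means=per_label,
        background=float(background_value),
        mean_intensity=overall,
        subtracted=max(overall - float(background_value), 0.0),
    )


def pla_compare(
    counts_by_condition: dict[str, Sequence[int]],
    reference: str,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Welch-test every condition against the reference; one summary row each."""
    if reference not in counts_by_condition:
        raise ValueError(f"reference condition {reference!r} not provided")
    rows = []
    ref = list(counts_by_condition[reference])
    for name, counts in counts_by_condition.items():
        summary = summarize_foci(counts, confidence)
        if name == reference:
            t = df = p = float("nan")
        else:
            t, df, p = welch_t_test(counts, ref)
        rows.append(
            {
                "condition": name,
                "n_cells": summary.n_cells,
                "mean_foci": summary.mean_foci,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "t_vs_reference": t,
                "df": df,
                "p_two_tailed": p,
            }
        )
    return pd.DataFrame(rows)
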