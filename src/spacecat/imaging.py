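"""Photoactivation image quantification.

A deliberately small, documented re-implementation of the usual
CellProfiler-style measurement chain: nuclei are segmented with a robust
background threshold, per-cell mean fluorescence is read out of the pre-
and post-photoactivation channels, the per-cell change in fluorescence
dF/F0 = (F_post - F_pre) / F_pre is computed, and cells inside vs outside
the photoactivation mask are compared with a two-sample t test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import gaussian
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "assign_cells",
    "compute_dff",
    "compare_inside_outside",
    "quantify_field",
]


@dataclass
class SegmentationParams:
    """Robust-background segmentation settings.

    The threshold is mean + threshold_sd_multiplier * SD of pixel
    intensities after trimming trim_fraction from each tail, computed on a
    Gaussian-smoothed copy of the image (sigma = smoothing_scale pixels).
    Objects smaller than min_object_pixels are discarded.
    """

    trim_fraction: float = 0.05
    threshold_sd_multiplier: float = 3.0
    min_object_pixels: int = 9
    smoothing_scale: float = 1.0

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.min_object_pixels < 0:
            raise ValueError("min_object_pixels must be non-negative")
        if self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be non-negative")


def segment_nuclei(nuclei_image: np.ndarray,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Label nuclei by robust-background thresholding.

    Returns an integer label grid (background 0). An empty or all-flat
    image yields zero objects; a saturated image triggers a warning.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclei_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei image must be 2-D")
    if img.size == 0:
        return np.zeros_like(img, dtype=np.int32)
    if np.any(img < 0):
        raise ValueError("nuclei image must be non-negative")
    if img.size and np.all(img == img.flat[0]) and img.flat[0] > 0:
        warnings.warn("nuclei image is constant/saturated; no objects found")
        return np.zeros_like(img, dtype=np.int32)

    smoothed = gaussian(img, sigma=params.smoothing_scale,
                        preserve_range=True) if params.smoothing_scale > 0 else img
    flat = np.sort(smoothed.ravel())
    lo = int(np.floor(params.trim_fraction * flat.size))
    hi = flat.size - lo
    trimmed = flat[lo:hi]
    threshold = trimmed.mean() + params.threshold_sd_multiplier * trimmed.std()
    labels = cc_label(smoothed > threshold, connectivity=2)
    if params.min_object_pixels > 1:
        sizes = np.bincount(labels.ravel())
        too_small = np.flatnonzero(sizes < params.min_object_pixels)
        labels[np.isin(labels, too_small)] = 0
        labels = cc_label(labels > 0, connectivity=2)
    return labels.astype(np.int32)


def assign_cells(labels: np.ndarray, signal_image: np.ndarray) -> pd.DataFrame:
    """Per-label mean intensity and centroid of a signal channel.

    Returns a DataFrame indexed by cell_id with columns centroid_row,
    centroid_col and mean (arithmetic mean of the signal pixels under each
    label).
    """
    labels = np.asarray(labels)
    signal = np.asarray(signal_image, dtype=float)
    if labels.shape != signal.shape:
        raise ValueError(
            f"label grid {labels.shape} and signal image {signal.shape} "
            "shapes differ"
        )
    ids = np.arange(1, labels.max() + 1) if labels.max() > 0 else np.array([], int)
    if ids.size == 0:
        return pd.DataFrame(columns=["centroid_row", "centroid_col", "mean"])
    means = ndimage.mean(signal, labels=labels, index=ids)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(signal),
                                                labels=labels, index=ids))
    return pd.DataFrame(
        {
            "centroid_row": centroids[:, 0],
            "centroid_col": centroids[:, 1],
            "mean": means,
        },
        index=pd.Index(ids, name="cell_id"),
    )


def compute_dff(f_pre: pd.Series | np.ndarray,
                f_post: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-cell dF/F0 = (F_post - F_pre) / F_pre.

    Cells with F_pre <= 0 are flagged (``valid = False``), excluded from
    the dff column (NaN) and logged, rather than raising.
    """
    pre = np.asarray(f_pre, dtype=float)
    post = np.asarray(f_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("F_pre and F_post must be the same length")
    valid = pre > 0
    dff = np.full(pre.shape, np.nan)
    dff[valid] = (post[valid] - pre[valid]) / pre[valid]
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d cell(s) excluded from dF/F0: F_pre <= 0", n_bad)
    index = f_pre.index if isinstance(f_pre, pd.Series) else None
    return pd.DataFrame({"F_pre": pre, "F_post": post, "dff": dff,
                         "valid": valid}, index=index)


def compare_inside_outside(dff: np.ndarray, in_mask: np.ndarray,
                           variant: str = "student"):
    """Two-sample t test of dF/F0 for in-mask vs out-of-mask cells.

    ``variant`` is "student" (pooled variance, the default) or "welch".
    Returns ``(t_statistic, p_two_sided, n_inside, n_outside)``.
    """
    dff = np.asarray(dff, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    keep = ~np.isnan(dff)
    inside = dff[keep & in_mask]
    outside = dff[keep & ~in_mask]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError(
            f"need >= 2 cells per group (got {len(inside)} inside, "
            f"{len(outside)} outside)"
        )
    t, p = stats.ttest_ind(inside, outside, equal_var=(variant == "student"))
    return float(t), float(p), len(inside), len(outside)


def mask_membership(centroids_rc: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """In-mask flags for centroids (0-based row/col; pixel lookup)."""
    mask = np.asarray(mask, dtype=bool)
    rc = np.asarray(centroids_rc, dtype=float)
    rows = np.clip(np.round(rc[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(rc[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return mask[rows, cols]


def quantify_field(image_pre: np.ndarray, image_post: np.ndarray,
                   nuclei: np.ndarray, mask: np.ndarray,
                   params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment, measure and score a full pre/post photoactivation field.

    Returns a per-cell FluorescenceTable: centroid, F_pre, F_post, dff,
    in_mask (by centroid membership) and validity flag.
    """
    labels = segment_nuclei(nuclei, params)
    pre_tab = assign_cells(labels, image_pre)
    post_tab = assign_cells(labels, image_post)
    table = compute_dff(pre_tab["mean"], post_tab["mean"])
    table.insert(0, "centroid_row", pre_tab["centroid_row"])
    table.insert(1, "centroid_col", pre_tab["centroid_col"])
    table["in_mask"] = mask_membership(
        pre_tab[["centroid_row", "centroid_col"]].to_numpy(), mask
    )
    table.index.name = "cell_id"
    return table
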