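"""Region-of-interest construction and per-subject feature extraction.

Anatomical gray/white-matter and sagittal-sinus masks are inputs (segmentation
and atlas registration are upstream, external steps). Here they are eroded
with a box kernel against partial-volume contamination, the high-signal
sagittal-sinus ROI is cut at the 90th percentile of the singleTI CBF map
within the sinus mask, and per-map ROI means are assembled into one feature
row per subject.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GridMismatchError, ValidationError

__all__ = ["ROISet", "erode_mask", "high_signal_roi", "roi_mean", "extract_features"]


@dataclass
class ROISet:
    """The three analysis masks plus the derived high-signal sinus ROI."""
    gm: np.ndarray
    wm: np.ndarray
    sinus_full: np.ndarray
    sinus_high: Optional[np.ndarray] = None
    coverage: float = float("nan")


def erode_mask(mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Morphological erosion with a cubic box structuring element.

    For even widths the box has no central voxel; the convention used is
    scipy's, with the origin at index ``width // 2`` of the box, i.e. the
    neighbourhood offsets run from ``-(width//2)`` to ``width - 1 - width//2``
    (for width 2: offsets {-1, 0} on each axis, so a solid cube of side n
    erodes to side n-1). The result may be empty, which is warned, not fatal.
    """
    mask = np.asarray(mask, dtype=bool)
    if width < 1:
        raise ValidationError(f"width must be >= 1, got {width!r}")
    if not mask.any():
        raise ValidationError("erode_mask requires a non-empty mask")
    if width == 1:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=np.ones((width,) * mask.ndim))
    if not out.any():
        warnings.warn(f"erosion with width {width} emptied the mask", stacklevel=2)
    return out


def high_signal_roi(cbf_map: np.ndarray, sinus_mask: np.ndarray,
                    percentile: float = 90.0,
                    subject_id: str = "?") -> tuple[np.ndarray, float]:
    """Upper-tail sinus ROI from the (unmasked) singleTI CBF map.

    The threshold is the given percentile (linear-interpolation definition) of
    the finite CBF values inside the sinus mask; retained voxels are those
    with value >= threshold, restricting analysis to the regions of highest
    venous signal. Returns ``(mask, threshold)``.
    """
    cbf_map = np.asarray(cbf_map, dtype=float)
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if cbf_map.shape != sinus_mask.shape:
        raise GridMismatchError(
            f"CBF map grid {cbf_map.shape} != sinus mask grid {sinus_mask.shape}")
    valid = sinus_mask & np.isfinite(cbf_map)
    n = int(valid.sum())
    if n < 10:
        raise ValidationError(
            f"subject {subject_id}: only {n} finite sinus voxels (need >= 10) "
            "for the percentile threshold")
    threshold = float(np.percentile(cbf_map[valid], percentile, method="linear"))
    return valid & (cbf_map >= threshold), threshold


def roi_mean(map3d: np.ndarray, roi: np.ndarray) -> tuple[float, int, float]:
    """Mean over finite map values inside the ROI.

    Returns ``(mean, n_voxels, coverage)`` with coverage the fraction of ROI
    voxels carrying finite values. Empty intersection gives NaN, 0 voxels and
    coverage 0 rather than an error.
    """
    map3d = np.asarray(map3d, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if map3d.shape != roi.shape:
        raise GridMismatchError(
            f"map grid {map3d.shape} != roi grid {roi.shape}")
    n_roi = int(roi.sum())
    vals = map3d[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or n_roi == 0:
        return math.nan, 0, 0.0
    return float(vals.mean()), int(vals.size), float(vals.size / n_roi)


def extract_features(maps_by_sequence: Mapping[str, Mapping[str, np.ndarray]],
                     rois: ROISet, subject_id: str = "?") -> pd.Series:
    """Assemble one per-subject row of ROI-mean hemodynamics.

    ``maps_by_sequence`` maps sequence keys to their parameter maps:
    ``{"singleTI": {"cbf": ...}, "multiTI": {"cbf": ..., "bat": ...}}``.
    A missing sequence leaves its features missing (NaN); the row is retained.
    Feature names tag the map family (``cbf_sti`` / ``cbf_mti`` / ``bat_mti``)
    and region (gm / wm / sinus = high-signal sagittal sinus).
    """
    if rois.sinus_high is None:
        raise ValidationError("rois.sinus_high not set; build it with high_signal_roi")
    regions = {"gm": rois.gm, "wm": rois.wm, "sinus": rois.sinus_high}
    families = {
        ("singleTI", "cbf"): "cbf_sti",
        ("multiTI", "cbf"): "cbf_mti",
        ("multiTI", "bat"): "bat_mti",
    }
    row: dict[str, float] = {"subject_id": subject_id}
    for (seq, map_name), prefix in families.items():
        seq_maps = maps_by_sequence.get(seq) or {}
        the_map = seq_maps.get(map_name)
        for region, mask in regions.items():
            col = f"{prefix}_{region}"
            if the_map is None:
                row[col] = math.nan
                row[f"{col}_n"] = 0
                row[f"{col}_coverage"] = math.nan
            else:
                mean, n, cov = roi_mean(the_map, mask)
                row[col] = mean
                row[f"{col}_n"] = n
                row[f"{col}_coverage"] = cov
    return pd.Series(row)
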