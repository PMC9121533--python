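"""Difference-signal preprocessing: averaging, background noise, voxel reliability.

EPI difference images carry ghost-free air in the four in-plane corners of the
field of view; the noise statistics measured there calibrate the reliability
threshold used to exclude voxels whose signal never rises above background.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "ASLSeries",
    "BackgroundStats",
    "mean_difference",
    "background_stats",
    "reliable_voxel_mask",
    "center_of_mass_drift",
]


@dataclass
class ASLSeries:
    """A 4D stack of difference volumes plus the matching M0 volume.

    ``kind`` is ``"singleTI"`` (volumes are repeats) or ``"multiTI"`` (one
    volume per inflow time, ``inflow_times`` in seconds, same order).
    """
    data: np.ndarray                 # (x, y, z, volume)
    m0: np.ndarray                   # (x, y, z)
    kind: str
    inflow_times: Optional[np.ndarray] = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"series data must be 4D, got {self.data.ndim}D")
        if self.m0.shape != self.data.shape[:3]:
            raise ValidationError(
                f"m0 grid {self.m0.shape} != series grid {self.data.shape[:3]}")
        if self.kind not in ("singleTI", "multiTI"):
            raise ValidationError(f"unknown series kind {self.kind!r}")
        if self.kind == "multiTI":
            if self.inflow_times is None:
                raise ValidationError("multiTI series requires inflow_times")
            self.inflow_times = np.asarray(self.inflow_times, dtype=float)
            if len(self.inflow_times) != self.data.shape[3]:
                raise ValidationError(
                    f"{len(self.inflow_times)} inflow times for "
                    f"{self.data.shape[3]} volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class BackgroundStats:
    """Pooled noise statistics from the four corner background boxes."""
    mean: float
    sd: float
    n_voxels: int
    boxes: tuple[tuple[slice, slice], ...]

    @property
    def threshold(self) -> float:
        """Default reliability threshold, mean + 1 SD."""
        return self.mean + self.sd


def mean_difference(series: ASLSeries) -> np.ndarray:
    """Voxel-wise mean over the repeats of a singleTI series."""
    if series.kind != "singleTI":
        raise TypeError("mean_difference expects a singleTI (repeated) series")
    return series.data.mean(axis=3)


def _corner_boxes(nx: int, ny: int, width: int) -> tuple[tuple[slice, slice], ...]:
    return tuple((xs, ys)
                 for xs in (slice(0, width), slice(nx - width, nx))
                 for ys in (slice(0, width), slice(ny - width, ny)))


def background_stats(series: ASLSeries, width: int = 5,
                     tissue_mask: Optional[np.ndarray] = None) -> BackgroundStats:
    """Noise mean/SD from four width x width in-plane corner squares.

    Statistics are pooled over all slices and all volumes of the series (the
    corner squares sit in ghost-free air on every slice). If a tissue mask is
    given, overlap with any corner box raises a warning: the boxes would no
    longer measure pure background.
    """
    nx, ny, nz = series.shape
    if min(nx, ny) < 3 * width:
        raise ValidationError(
            f"in-plane matrix {nx}x{ny} too small for corner width {width}")
    boxes = _corner_boxes(nx, ny, width)
    if tissue_mask is not None:
        for xs, ys in boxes:
            if np.any(tissue_mask[xs, ys, :]):
                warnings.warn("corner background box overlaps the tissue mask",
                              stacklevel=2)
                break
    samples = np.concatenate([series.data[xs, ys, :, :].ravel() for xs, ys in boxes])
    n = samples.size
    assert n == 4 * width * width * nz * series.n_volumes
    return BackgroundStats(mean=float(samples.mean()),
                           sd=float(samples.std(ddof=1)),
                           n_voxels=n, boxes=boxes)


def reliable_voxel_mask(series: ASLSeries, stats: BackgroundStats,
                        multiplier: float = 1.0) -> np.ndarray:
    """Voxels whose signal rises above background on at least one volume.

    A voxel is reliable iff max over volumes of its difference signal is
    strictly greater than ``mean + multiplier * sd`` of the ghost-free
    background. The comparison is strict, so exact ties are excluded.
    """
    if multiplier < 0:
        raise ValidationError("multiplier must be >= 0")
    threshold = stats.mean + multiplier * stats.sd
    return series.data.max(axis=3) > threshold


def center_of_mass_drift(series: ASLSeries) -> float:
    """Max volume-to-volume centre-of-mass displacement, in voxels.

    QC hook mirroring a motion-exclusion policy: co-registration itself is out
    of scope, but a series whose signal centre drifts beyond a caller-chosen
    limit can be flagged for exclusion.
    """
    coms = []
    for v in range(series.n_volumes):
        vol = np.abs(series.data[..., v])
        total = vol.sum()
        coms.append(np.array(ndimage.center_of_mass(vol)) if total > 0
                    else np.zeros(3))
    coms = np.asarray(coms)
    if len(coms) < 2:
        return 0.0
    return float(np.max(np.linalg.norm(np.diff(coms, axis=0), axis=1)))
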