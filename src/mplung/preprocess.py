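"""Series/mask containers, motion compensation, and fallback segmentation.

The acquisition is multi-slice 2D: each coronal slice is an independent
~150-frame cine.  Motion compensation therefore runs per slice, aligning
every frame to a fixed baseline frame in the mid-respiratory state by an
integer in-plane translation (the spectral stage only needs approximate
voxel correspondence).  Lung masks normally come from an external
segmentation; :func:`segment_lungs_fallback` provides a naive Otsu-based
stand-in for phantom data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening
from skimage.segmentation import clear_border

from .errors import ConfigurationError, RegistrationError, SegmentationError

logger = logging.getLogger(__name__)

# mask label convention, shared with every NIfTI this package writes
BACKGROUND, RIGHT, LEFT, HEART = 0, 1, 2, 3

#: minimum normalized cross-correlation peak to trust a shift estimate
NCC_CONFIDENCE = 0.3


@dataclass
class DynamicSeries:
    """Multi-slice dynamic image series with acquisition timing.

    ``data`` is indexed ``(slice, time, row, col)`` in arbitrary signal
    units.  ``shifts`` holds the applied per-slice per-frame (dy, dx)
    correction in voxels once the series is registered.
    """

    data: np.ndarray
    frame_rate: float
    voxel_size: tuple[float, float, float] = (3.3, 3.3, 12.0)
    registered: bool = False
    shifts: np.ndarray | None = None  # (n_slices, n_frames, 2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ConfigurationError(
                f"data must be (slice, time, row, col); got shape "
                f"{self.data.shape}"
            )
        if self.frame_rate <= 0:
            raise ConfigurationError(f"frame_rate={self.frame_rate} must be > 0")
        if self.shifts is not None and not np.all(np.isfinite(self.shifts)):
            raise ConfigurationError("shifts must be finite")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def duration_s(self) -> float:
        """Time from first to last frame, in seconds."""
        return (self.n_frames - 1) / self.frame_rate


@dataclass
class LungMask:
    """Side-labeled voxel labels on the series grid (slice, row, col)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ConfigurationError(
                f"labels must be (slice, row, col); got {self.labels.shape}"
            )
        bad = set(np.unique(self.labels)) - {BACKGROUND, RIGHT, LEFT, HEART}
        if bad:
            raise ConfigurationError(f"unknown mask labels: {sorted(bad)}")

    @property
    def lung(self) -> np.ndarray:
        return (self.labels == RIGHT) | (self.labels == LEFT)

    def side(self, side: str) -> np.ndarray:
        lab = {"right": RIGHT, "left": LEFT}.get(side)
        if lab is None:
            raise ConfigurationError(f"side={side!r} must be 'left' or 'right'")
        return self.labels == lab

    @property
    def slice_counts(self) -> np.ndarray:
        """Lung voxel count per slice."""
        return self.lung.sum(axis=(1, 2))


def _lung_mean_per_frame(series: DynamicSeries, mask: LungMask) -> np.ndarray:
    lung = mask.lung
    if not lung.any():
        raise ConfigurationError("lung mask is empty")
    total = np.zeros(series.n_frames)
    for s in range(series.n_slices):
        sel = lung[s]
        if sel.any():
            # accumulate in float64: near-ties in the median distance must
            # not depend on the storage dtype
            total += series.data[s][:, sel].astype(np.float64).sum(axis=1)
    return total / lung.sum()


def select_baseline_frame(series: DynamicSeries, mask: LungMask) -> int:
    """Frame whose whole-lung mean is closest to the temporal median.

    This is the mid-respiratory state: the lung mean oscillates with the
    breathing cycle and its median sits between inspiration and expiration.
    Ties break toward the earliest frame.
    """
    if series.n_frames < 3:
        raise ConfigurationError("need at least 3 frames to pick a baseline")
    means = _lung_mean_per_frame(series, mask)
    med = float(np.median(means))
    return int(np.argmin(np.abs(means - med)))


def _ncc_peak_shift(frame: np.ndarray, base: np.ndarray) -> tuple[int, int, float]:
    """Integer circular shift maximizing normalized cross-correlation.

    Returns (dy, dx, peak) such that ``frame`` best matches ``base`` when
    rolled by (-dy, -dx); peak is the NCC value in [-1, 1].
    """
    f = frame - frame.mean()
    b = base - base.mean()
    denom = np.linalg.norm(f) * np.linalg.norm(b)
    if denom == 0:
        return 0, 0, 1.0
    corr = np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(b))).real
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    h, w = corr.shape
    dy = iy - h if iy > h // 2 else iy
    dx = ix - w if ix > w // 2 else ix
    return int(dy), int(dx), float(corr[iy, ix] / denom)


def register_translation(
    series: DynamicSeries,
    baseline: int,
    confidence: float = NCC_CONFIDENCE,
) -> DynamicSeries:
    """Align every frame of every slice to the baseline frame by integer
    translation; out-of-frame voxels are filled with edge values.

    Shift estimates with an NCC peak below ``confidence`` (e.g. pure-noise
    frames) are replaced by zero and logged; estimates larger than a
    quarter of the grid raise :class:`RegistrationError`.
    """
    if not (0 <= baseline < series.n_frames):
        raise ConfigurationError(f"baseline frame {baseline} out of range")
    h, w = series.grid
    max_dy, max_dx = h // 4, w // 4
    out = np.empty_like(series.data)
    shifts = np.zeros((series.n_slices, series.n_frames, 2), dtype=int)
    n_low_conf = 0
    for s in range(series.n_slices):
        base = series.data[s, baseline].astype(float)
        for t in range(series.n_frames):
            frame = series.data[s, t].astype(float)
            dy, dx, peak = _ncc_peak_shift(frame, base)
            if peak < confidence:
                dy = dx = 0
                n_low_conf += 1
            elif abs(dy) > max_dy or abs(dx) > max_dx:
                raise RegistrationError(
                    f"slice {s} frame {t}: estimated shift ({dy}, {dx}) "
                    f"exceeds a quarter of the grid ({h}x{w})"
                )
            if dy or dx:
                out[s, t] = ndimage.shift(series.data[s, t], (-dy, -dx),
                                          order=0, mode="nearest")
            else:
                out[s, t] = series.data[s, t]
            shifts[s, t] = (-dy, -dx)
    if n_low_conf:
        logger.warning("registration: %d low-confidence frames left unshifted",
                       n_low_conf)
    return replace(series, data=out, registered=True, shifts=shifts)


def segment_lungs_fallback(mean_image: np.ndarray,
                           opening_radius: int = 1) -> LungMask:
    """Naive lung segmentation of a temporal-mean image.

    Lungs are the two largest dark (sub-Otsu) components not connected to
    the in-plane image border (which excludes surrounding air).  Sides are
    labeled by centroid column: the lower-column lung gets the RIGHT label,
    matching this package's mask convention.  Intended for phantom data
    only — supply a real mask for anything else.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise ConfigurationError(f"mean image must be 2D/3D; got {img.ndim}D")
    if img.max() == img.min():
        raise SegmentationError("blank image: cannot segment; supply a mask")
    low = img < threshold_otsu(img)
    interior = np.stack([clear_border(low[s]) for s in range(img.shape[0])])
    if opening_radius > 0:
        selem = disk(opening_radius)
        interior = np.stack(
            [opening(interior[s], selem) for s in range(img.shape[0])]
        )
    comps = cc_label(interior, connectivity=1)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    if np.count_nonzero(sizes) < 2:
        raise SegmentationError(
            "fewer than two lung candidates found; supply a lung mask"
        )
    first, second = np.argsort(sizes)[::-1][:2]
    cols = np.indices(comps.shape)[2]
    cent = {lab: cols[comps == lab].mean() for lab in (first, second)}
    right_lab = min(cent, key=cent.get)
    left_lab = second if right_lab == first else first
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[comps == right_lab] = RIGHT
    labels[comps == left_lab] = LEFT
    return LungMask(labels)
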