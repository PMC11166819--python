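"""Defect burden metrics: VDP, QDP, VQD_match, side splits, and DDI.

Conventions:

* VDP/QDP per side use the *whole-lung* voxel count as denominator, so the
  two side values add up exactly to the whole-lung percentage.
* VQD_match and DDI per side use the side's own voxels as reference
  region (side VQD values average, rather than sum, to the whole-lung
  value).
* The defect distribution index (DDI) is computed in-plane per slice
  (multi-slice 2D acquisition with thick slices): for each defect voxel,
  the local defect density within a disc of radius R (default 3 voxels)
  is weighted by the square root of its 8-connected component size; the
  slice score is the mean over defect voxels and slices are combined
  weighted by defect count.  DDI is in arbitrary units, zero iff there
  are no defect voxels, and grows when defects are dense and aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .errors import ConfigurationError
from .preprocess import LungMask

DDI_RADIUS = 3


@dataclass
class DefectMetrics:
    """All defect metrics for one subject, with backing voxel counts."""

    vdp: float
    qdp: float
    vqd_match: float
    vdp_side: dict[str, float]
    qdp_side: dict[str, float]
    vqd_side: dict[str, float]
    ddi_v: float
    ddi_q: float
    ddi_v_side: dict[str, float]
    ddi_q_side: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)


def _check_subset(defect: np.ndarray, lung: np.ndarray) -> None:
    if defect.shape != lung.shape:
        raise ConfigurationError("defect and lung masks differ in shape")
    if (defect & ~lung).any():
        raise ConfigurationError("defect mask extends outside the lung")


def defect_percentage(defect: np.ndarray, lung: np.ndarray) -> float:
    """100 * |defect| / |lung| across all slices."""
    _check_subset(defect, lung)
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ConfigurationError("lung mask is empty")
    return 100.0 * float(defect.sum()) / n_lung


def matched_defect_percentage(v_defect: np.ndarray, q_defect: np.ndarray,
                              lung: np.ndarray) -> float:
    """100 * |v_defect AND q_defect| / |lung|."""
    _check_subset(v_defect, lung)
    _check_subset(q_defect, lung)
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ConfigurationError("lung mask is empty")
    return 100.0 * float((v_defect & q_defect).sum()) / n_lung


def side_keys(hernia_side: str | None) -> dict[str, str]:
    """Map anatomical sides to output keys.

    With a hernia side given, sides are relabeled affected/non_affected;
    without one, left/right keys are kept.
    """
    if hernia_side in ("left", "right"):
        other = "right" if hernia_side == "left" else "left"
        return {hernia_side: "affected", other: "non_affected"}
    if hernia_side in (None, "none"):
        return {"left": "left", "right": "right"}
    raise ConfigurationError(f"hernia_side={hernia_side!r} must be "
                             "left|right|none")


def side_specific_percentages(defect: np.ndarray, mask: LungMask,
                              hernia_side: str | None = None
                              ) -> dict[str, float]:
    """Per-side defect percentage with the whole-lung denominator.

    The two values sum exactly to the whole-lung defect percentage.
    """
    lung = mask.lung
    _check_subset(defect, lung)
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ConfigurationError("lung mask is empty")
    keys = side_keys(hernia_side)
    out = {}
    for anat, key in keys.items():
        side = mask.side(anat)
        if not side.any():
            raise ConfigurationError(f"mask has no {anat} lung label")
        out[key] = 100.0 * float((defect & side).sum()) / n_lung
    return out


def _disc_kernel(radius: float) -> np.ndarray:
    r_int = int(np.floor(radius))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    kern = (yy**2 + xx**2) <= radius**2
    kern[r_int, r_int] = False  # exclude the voxel itself
    return kern


def defect_distribution_index(defect: np.ndarray, lung: np.ndarray,
                              radius: float = DDI_RADIUS) -> float:
    """Clustering index of the defect voxels (arbitrary units, >= 0).

    Per slice, each defect voxel i scores ``rho_i * sqrt(c_i)`` where
    ``rho_i`` is the fraction of the punctured disc of radius ``radius``
    around i occupied by other defect voxels and ``c_i`` the size of its
    8-connected defect component; the overall index is the defect-count
    weighted mean of slice means (equivalently the mean score over all
    defect voxels).  Zero iff the defect set is empty.
    """
    if radius <= 0:
        raise ConfigurationError(f"radius={radius} must be > 0")
    _check_subset(defect, lung)
    if not defect.any():
        return 0.0
    kern = _disc_kernel(radius)
    denom = int(kern.sum())
    total_score = 0.0
    total_count = 0
    for s in range(defect.shape[0]):
        d = defect[s]
        if not d.any():
            continue
        neigh = ndimage.convolve(d.astype(float), kern.astype(float),
                                 mode="constant", cval=0.0)
        rho = neigh[d] / denom
        comps = cc_label(d, connectivity=2)
        sizes = np.bincount(comps.ravel())
        c = sizes[comps[d]]
        total_score += float((rho * np.sqrt(c)).sum())
        total_count += int(d.sum())
    return total_score / total_count


def compute_defect_metrics(v_defect: np.ndarray, q_defect: np.ndarray,
                           mask: LungMask, hernia_side: str | None = None,
                           ddi_radius: float = DDI_RADIUS) -> DefectMetrics:
    """Assemble every defect metric for one subject."""
    lung = mask.lung
    keys = side_keys(hernia_side)
    vqd_side: dict[str, float] = {}
    ddi_v_side: dict[str, float] = {}
    ddi_q_side: dict[str, float] = {}
    counts: dict[str, int] = {"lung": int(lung.sum()),
                              "v_defect": int(v_defect.sum()),
                              "q_defect": int(q_defect.sum()),
                              "vq_match": int((v_defect & q_defect).sum())}
    for anat, key in keys.items():
        side = mask.side(anat)
        n_side = int(side.sum())
        counts[f"lung_{key}"] = n_side
        counts[f"v_defect_{key}"] = int((v_defect & side).sum())
        counts[f"q_defect_{key}"] = int((q_defect & side).sum())
        if n_side == 0:
            raise ConfigurationError(f"mask has no {anat} lung label")
        vqd_side[key] = 100.0 * float((v_defect & q_defect & side).sum()) \
            / n_side
        ddi_v_side[key] = defect_distribution_index(v_defect & side, side,
                                                    ddi_radius)
        ddi_q_side[key] = defect_distribution_index(q_defect & side, side,
                                                    ddi_radius)
    return DefectMetrics(
        vdp=defect_percentage(v_defect, lung),
        qdp=defect_percentage(q_defect, lung),
        vqd_match=matched_defect_percentage(v_defect, q_defect, lung),
        vdp_side=side_specific_percentages(v_defect, mask, hernia_side),
        qdp_side=side_specific_percentages(q_defect, mask, hernia_side),
        vqd_side=vqd_side,
        ddi_v=defect_distribution_index(v_defect, lung, ddi_radius),
        ddi_q=defect_distribution_index(q_defect, lung, ddi_radius),
        ddi_v_side=ddi_v_side,
        ddi_q_side=ddi_q_side,
        counts=counts,
    )
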