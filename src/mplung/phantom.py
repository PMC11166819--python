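"""Synthetic free-breathing dynamic series and synthetic cohort tables.

The dynamic phantom emulates a multi-slice coronal 2D acquisition of the
chest during free tidal breathing: every lung voxel carries a periodic
intensity modulation at the respiratory frequency (bulk density change
with inflation) and a weaker one at the cardiac frequency (pulsatile blood
volume), on top of a static anatomy image and Gaussian noise:

    S_v(t) = S0_v * (1 + a_v sin(2 pi f_resp t + phi)
                       + b_v sin(2 pi f_card t + psi)) + noise

``a_v`` and ``b_v`` are smooth spatial random fields (healthy lungs are
heterogeneous, so a relative-median defect rule yields a nonzero defect
percentage even without disease), multiplicatively attenuated inside a
plantable contiguous defect blob on one side.  A heart region between the
lungs carries cardiac-only modulation so the cardiac rate can be estimated
from a strong source.  Ground truth (masks, amplitude fields, frequencies,
planted bulk motion) is returned for recovery tests.

The cohort generator draws per-subject outcome tables from group-specific
normal distributions, with correlated per-side values, defaulting to the
published group summaries of the reference CDH cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_stats import CDH_COHORT_SUMMARIES, CDH_SIDE_SUMMARIES, GROUPS
from .errors import ConfigurationError
from .preprocess import BACKGROUND, HEART, LEFT, RIGHT, DynamicSeries, LungMask

#: baseline signal levels (arbitrary units)
S0_LUNG = 100.0
S0_BODY = 220.0
S0_HEART = 200.0
S0_AIR = 5.0
HEART_CARD_AMP = 0.10  # cardiac modulation fraction of the heart region


@dataclass
class PhantomConfig:
    n_slices: int = 10
    n_frames: int = 150
    frame_rate: float = 3.3  # Hz
    grid: tuple[int, int] = (96, 96)
    voxel_size: tuple[float, float, float] = (3.3, 3.3, 12.0)  # mm
    f_resp: float = 0.30  # Hz
    f_card: float = 1.25  # Hz
    resp_amp_mean: float = 0.12  # fraction of baseline
    card_amp_mean: float = 0.03
    amp_cv: float = 0.25  # CV of the spatial amplitude fields
    defect_side: str = "none"  # left | right | none
    defect_fraction: float = 0.0  # fraction of affected-side lung voxels
    defect_attenuation: float = 0.4  # amplitude factor inside defects
    defect_decouple_q: bool = False  # grow a separate perfusion defect blob
    noise_sd: float = 0.02  # fraction of lung baseline
    bulk_shift_amp: float = 0.0  # voxels of planted bulk translation
    seed: int = 0

    def validate(self) -> None:
        for name in ("resp_amp_mean", "card_amp_mean", "defect_fraction",
                     "defect_attenuation", "noise_sd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.amp_cv < 0:
            raise ConfigurationError(f"amp_cv={self.amp_cv} must be >= 0")
        if self.defect_side not in ("left", "right", "none"):
            raise ConfigurationError(
                f"defect_side={self.defect_side!r} must be left|right|none")
        if self.f_resp <= 0 or self.f_card <= 0 or self.f_resp >= self.f_card:
            raise ConfigurationError(
                f"require 0 < f_resp < f_card; got f_resp={self.f_resp}, "
                f"f_card={self.f_card}")
        if self.frame_rate <= 2 * self.f_card:
            raise ConfigurationError(
                f"frame_rate={self.frame_rate} must exceed 2*f_card="
                f"{2 * self.f_card} (sampling adequacy)")
        if self.n_frames < 8:
            raise ConfigurationError(f"n_frames={self.n_frames} too small")
        if self.n_slices < 1:
            raise ConfigurationError(f"n_slices={self.n_slices} must be >= 1")
        if min(self.grid) < 32:
            raise ConfigurationError(
                f"grid={self.grid} too small to hold two lung ellipses")


@dataclass
class PhantomTruth:
    """Ground truth emitted next to each phantom for recovery tests."""

    lung_mask: LungMask
    defect_mask_v: np.ndarray  # bool (slice, row, col)
    defect_mask_q: np.ndarray
    true_defect_fraction_by_side: dict[str, float]
    f_resp: float
    f_card: float
    amp_resp: np.ndarray  # per-voxel a_v (fraction of baseline)
    amp_card: np.ndarray
    bulk_shifts: np.ndarray  # planted (dy, dx) per frame
    s0: float
    phases: tuple[float, float]


def _ellipse(rows: int, cols: int, cy: float, cx: float,
             ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _anatomy(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Labels (slice, row, col) and static base image."""
    h, w = config.grid
    n_s = config.n_slices
    labels = np.zeros((n_s, h, w), dtype=np.uint8)
    body = np.zeros((n_s, h, w), dtype=bool)
    for s in range(n_s):
        # lungs taper toward the anterior/posterior slices
        scale = 0.60 + 0.40 * np.sin(np.pi * (s + 0.5) / n_s)
        thorax = _ellipse(h, w, 0.52 * h, 0.50 * w, 0.44 * h, 0.46 * w)
        right = _ellipse(h, w, 0.52 * h, 0.30 * w,
                         0.34 * h * scale, 0.16 * w * scale)
        left = _ellipse(h, w, 0.52 * h, 0.70 * w,
                        0.34 * h * scale, 0.16 * w * scale)
        body[s] = thorax
        heart = np.zeros((h, w), dtype=bool)
        if n_s // 4 <= s <= (3 * n_s) // 4:
            # heart sits between the lungs, carving a notch into the left one
            heart = _ellipse(h, w, 0.60 * h, 0.52 * w, 0.13 * h, 0.11 * w)
        labels[s][right & thorax & ~heart] = RIGHT
        labels[s][left & thorax & ~heart] = LEFT
        labels[s][heart & thorax] = HEART
    base = np.full((n_s, h, w), S0_AIR)
    base[body] = S0_BODY
    base[labels == HEART] = S0_HEART
    base[(labels == RIGHT) | (labels == LEFT)] = S0_LUNG
    return labels, base


def _smooth_amp_field(shape: tuple[int, ...], mean: float, cv: float,
                      region: np.ndarray, rng: np.random.Generator,
                      sigma: float = 4.0) -> np.ndarray:
    """Smoothed white noise rescaled to the target mean/CV on ``region``."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(1.0, sigma, sigma))
    vals = smooth[region]
    sd = vals.std()
    if sd == 0 or cv == 0:
        fld = np.full(shape, mean)
    else:
        fld = mean + (smooth - vals.mean()) / sd * (cv * mean)
    return np.clip(fld, 0.05 * mean if mean > 0 else 0.0, None)


def _grow_blob(side_mask: np.ndarray, target: int,
               rng: np.random.Generator) -> np.ndarray:
    """Contiguous 6-connected blob of ``target`` voxels grown from a random
    seed voxel inside ``side_mask`` (breadth-first)."""
    blob = np.zeros_like(side_mask)
    if target <= 0:
        return blob
    coords = np.argwhere(side_mask)
    start = tuple(coords[rng.integers(len(coords))])
    queue = [start]
    blob[start] = True
    count = 1
    head = 0
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
               (0, 0, 1), (0, 0, -1))
    shape = side_mask.shape
    while count < target and head < len(queue):
        cur = queue[head]
        head += 1
        for off in offsets:
            nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if not all(0 <= nxt[i] < shape[i] for i in range(3)):
                continue
            if side_mask[nxt] and not blob[nxt]:
                blob[nxt] = True
                queue.append(nxt)
                count += 1
                if count >= target:
                    break
    return blob


def generate_phantom_series(
    config: PhantomConfig,
) -> tuple[DynamicSeries, LungMask, PhantomTruth]:
    """Generate one synthetic dynamic series with ground truth.

    Deterministic for a fixed ``config.seed``: every emitted voxel is
    bit-exact across calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, base = _anatomy(config)
    mask = LungMask(labels)
    lung = mask.lung

    amp_resp = _smooth_amp_field(labels.shape, config.resp_amp_mean,
                                 config.amp_cv, lung, rng)
    amp_card = _smooth_amp_field(labels.shape, config.card_amp_mean,
                                 config.amp_cv, lung, rng)

    defect_v = np.zeros(labels.shape, dtype=bool)
    defect_q = np.zeros(labels.shape, dtype=bool)
    if config.defect_side != "none" and config.defect_fraction > 0:
        side = mask.side(config.defect_side)
        target = int(round(config.defect_fraction * side.sum()))
        defect_v = _grow_blob(side, target, rng)
        defect_q = defect_v.copy()
        if config.defect_decouple_q:
            defect_q = _grow_blob(side, target, rng)
    amp_resp = np.where(defect_v, amp_resp * config.defect_attenuation,
                        amp_resp)
    amp_card = np.where(defect_q, amp_card * config.defect_attenuation,
                        amp_card)

    phi, psi = rng.uniform(0.0, 2.0 * np.pi, size=2)
    t = np.arange(config.n_frames) / config.frame_rate
    sin_r = np.sin(2.0 * np.pi * config.f_resp * t + phi)
    sin_c = np.sin(2.0 * np.pi * config.f_card * t + psi)

    resp_field = np.where(lung, base * amp_resp, 0.0)
    card_field = np.where(lung, base * amp_card, 0.0)
    card_field[labels == HEART] = S0_HEART * HEART_CARD_AMP

    data = (base[:, None, :, :]
            + resp_field[:, None, :, :] * sin_r[None, :, None, None]
            + card_field[:, None, :, :] * sin_c[None, :, None, None])

    bulk_shifts = np.zeros((config.n_frames, 2), dtype=int)
    if config.bulk_shift_amp > 0:
        bulk_shifts[:, 0] = np.round(
            config.bulk_shift_amp * np.sin(2.0 * np.pi * config.f_resp * t
                                           + phi)).astype(int)
        for ti in range(config.n_frames):
            dy = bulk_shifts[ti, 0]
            if dy:
                data[:, ti] = ndimage.shift(
                    data[:, ti], (0, dy, 0), order=0, mode="nearest")

    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd * S0_LUNG, data.shape)

    series = DynamicSeries(data=data.astype(np.float32),
                           frame_rate=config.frame_rate,
                           voxel_size=config.voxel_size)
    fractions = {}
    for side_name in ("right", "left"):
        side = mask.side(side_name)
        fractions[side_name] = (float((defect_v & side).sum() / side.sum())
                                if side.any() else 0.0)
    truth = PhantomTruth(
        lung_mask=mask, defect_mask_v=defect_v, defect_mask_q=defect_q,
        true_defect_fraction_by_side=fractions,
        f_resp=config.f_resp, f_card=config.f_card,
        amp_resp=amp_resp * lung, amp_card=amp_card * lung,
        bulk_shifts=bulk_shifts, s0=S0_LUNG, phases=(float(phi), float(psi)),
    )
    return series, mask, truth


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort: group-specific normals for each
    outcome and correlated per-side draws.

    Defaults are the published group summaries of the reference cohort
    (13 controls / 7 small CDH / 6 large CDH).
    """

    outcomes: dict = field(
        default_factory=lambda: {
            o: {g: (m, sd) for g, (m, sd, _) in per_group.items()}
            for o, per_group in CDH_COHORT_SUMMARIES.items()
        })
    side_outcomes: dict = field(
        default_factory=lambda: {
            o: {g: dict(sides) for g, sides in per_group.items()}
            for o, per_group in CDH_SIDE_SUMMARIES.items()
        })
    n_per_group: dict = field(
        default_factory=lambda: {"control": 13, "small_CDH": 7,
                                 "large_CDH": 6})
    side_correlation: float = 0.5  # within-subject correlation of side values
    hernia_right_fraction: float = 0.15  # share of right-sided hernias
    seed: int = 0

    def validate(self) -> None:
        if not (-1.0 <= self.side_correlation <= 1.0):
            raise ConfigurationError(
                f"side_correlation={self.side_correlation} not in [-1, 1]")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ConfigurationError(
                    f"n_per_group[{g!r}]={n} must be >= 2 "
                    "(variance undefined otherwise)")
        for o, per_group in self.outcomes.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ConfigurationError(f"{o}/{g}: sd={sd} < 0")


def generate_cohort_table(config: CohortSimConfig) -> pd.DataFrame:
    """One row per synthetic subject: group label, hernia side, whole-lung
    outcomes, and per-side outcomes keyed ``_affected``/``_non_affected``.

    Controls carry ``hernia_side='none'``; their "affected" side is the
    left lung, matching the convention used for healthy comparisons.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rho = config.side_correlation
    rows = []
    for g in config.n_per_group:
        for i in range(config.n_per_group[g]):
            row: dict = {"subject_id": f"{g}_{i:03d}", "group": g}
            if g == "control":
                row["hernia_side"] = "none"
            else:
                row["hernia_side"] = ("right"
                                      if rng.random()
                                      < config.hernia_right_fraction
                                      else "left")
            for o, per_group in config.outcomes.items():
                if g in per_group:
                    m, sd = per_group[g]
                    row[o] = m + sd * rng.standard_normal()
                else:
                    row[o] = np.nan
            for o, per_group in config.side_outcomes.items():
                if g not in per_group:
                    continue
                m1, s1 = per_group[g]["non_affected"]
                m2, s2 = per_group[g]["affected"]
                z1, z2 = rng.standard_normal(2)
                row[f"{o}_non_affected"] = m1 + s1 * z1
                row[f"{o}_affected"] = m2 + s2 * (
                    rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2)
            rows.append(row)
    return pd.DataFrame(rows)
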