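"""Per-voxel functional maps and the relative-median defect rule.

Every lung voxel's time series is decomposed with the matrix pencil; the
component amplitude at the respiratory rate, normalized by the voxel's
temporal mean signal, is its *fractional ventilation* (FV), and the raw
amplitude at the cardiac rate is its *relative perfusion* (Q).  A voxel is
called defective when its map value falls strictly below ``0.70 x`` the
median over the segmented lung area of its own coronal slice — a
per-slice, scale-invariant rule, so the perfusion map needs no absolute
calibration.

The voxel loop is vectorized: Hankel stacks for chunks of voxels go
through batched SVD / eigenvalue / least-squares calls, with a fixed model
order (default 10: baseline + respiratory + cardiac pairs plus slack for
noise poles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError
from .mp_spectral import MATCH_TOL_HZ, CardinalFrequencies
from .preprocess import DynamicSeries, LungMask

logger = logging.getLogger(__name__)

THRESHOLD_FACTOR = 0.70
VOXEL_ORDER = 10  # pencil model order for single-voxel fits
CHUNK = 512  # voxels per batched linear-algebra call


@dataclass
class FunctionalMaps:
    """Fractional-ventilation and perfusion-amplitude images.

    Values are defined on lung voxels and zero elsewhere.
    """

    fv: np.ndarray  # (slice, row, col), unitless >= 0
    q: np.ndarray  # signal units >= 0
    f_resp: float
    f_card: float

    def __post_init__(self) -> None:
        if self.fv.shape != self.q.shape:
            raise ConfigurationError("fv and q must share a grid")


@dataclass
class DefectMasks:
    """Boolean defect masks inside the lung; vq_match = both defective."""

    v_defect: np.ndarray
    q_defect: np.ndarray
    threshold_factor: float = THRESHOLD_FACTOR

    @property
    def vq_match(self) -> np.ndarray:
        return self.v_defect & self.q_defect


def _batch_amplitudes(x: np.ndarray, frame_rate: float, f_targets,
                      pencil_l: int, order: int,
                      tol: float) -> np.ndarray:
    """Amplitude of each target frequency for each row of ``x``.

    Demeans each series, runs the pencil with a fixed order on batched
    Hankel stacks, and reads the real-signal amplitude (2|c|) of the pole
    nearest each positive target frequency within ``tol`` Hz (0 if none).
    Returns an array (n_series, n_targets).
    """
    v, n = x.shape
    means = x.mean(axis=1)
    xd = x - means[:, None]
    hank = sliding_window_view(xd, pencil_l + 1, axis=1)  # (v, n-L, L+1)
    m = min(order, pencil_l)
    out = np.zeros((v, len(f_targets)))
    for lo in range(0, v, CHUNK):
        hi = min(lo + CHUNK, v)
        _, _, vh = np.linalg.svd(hank[lo:hi], full_matrices=False)
        vmat = vh[:, :m, :].transpose(0, 2, 1)  # (b, L+1, m)
        v1, v2 = vmat[:, :-1, :], vmat[:, 1:, :]
        g = v1.transpose(0, 2, 1) @ v1
        g += 1e-12 * np.trace(g, axis1=1, axis2=2)[:, None, None] \
            * np.eye(m)[None]
        a = np.linalg.solve(g, v1.transpose(0, 2, 1) @ v2)
        z = np.linalg.eigvals(a)  # (b, m)
        # tame nonphysical pole magnitudes so z**n cannot overflow
        mag = np.abs(z)
        z = np.where(mag > 1.1, z / mag * 1.1, z)
        z = np.where(mag < 0.5, 0.5 * np.exp(1j * np.angle(z)), z)
        nn = np.arange(n)
        vand = z[:, None, :] ** nn[None, :, None]  # (b, n, m)
        vh_c = vand.conj().transpose(0, 2, 1)
        gz = vh_c @ vand
        gz += 1e-10 * np.abs(np.trace(gz, axis1=1, axis2=2))[:, None, None] \
            * np.eye(m)[None]
        c = np.linalg.solve(gz, vh_c @ xd[lo:hi, :, None].astype(complex))
        c = c[..., 0]  # (b, m)
        freqs = np.angle(z) * frame_rate / (2.0 * np.pi)
        for j, f0 in enumerate(f_targets):
            d = np.where(freqs > 0, np.abs(freqs - f0), np.inf)
            nearest = np.argmin(d, axis=1)
            amp = 2.0 * np.abs(c[np.arange(hi - lo), nearest])
            ok = d[np.arange(hi - lo), nearest] <= tol
            out[lo:hi, j] = np.where(ok, amp, 0.0)
    return out


def compute_functional_maps(
    series: DynamicSeries,
    mask: LungMask,
    freqs: CardinalFrequencies,
    pencil_L: int | None = None,
    order: int = VOXEL_ORDER,
    tol: float = MATCH_TOL_HZ,
    normalizer: str = "mean",
) -> FunctionalMaps:
    """Fractional-ventilation and perfusion maps for all lung voxels.

    ``fv = A(f_resp) / mean(S)`` per voxel; ``q = A(f_card)`` (raw
    amplitude — the downstream defect rule is scale-invariant per slice).
    Voxels with non-positive mean signal get fv = 0 with a logged warning.
    """
    if not series.registered:
        raise ConfigurationError("series must be registered before mapping")
    if normalizer != "mean":
        raise ConfigurationError(
            f"normalizer={normalizer!r}: only 'mean' is implemented")
    n = series.n_frames
    pencil_l = pencil_L if pencil_L is not None else n // 3
    lung = mask.lung
    fv = np.zeros(lung.shape)
    q = np.zeros(lung.shape)
    n_bad = 0
    for s in range(series.n_slices):
        sel = lung[s]
        if not sel.any():
            continue
        x = series.data[s][:, sel].T.astype(float)  # (n_voxels, n_frames)
        amps = _batch_amplitudes(x, series.frame_rate,
                                 (freqs.f_resp, freqs.f_card),
                                 pencil_l, order, tol)
        means = x.mean(axis=1)
        bad = means <= 0
        n_bad += int(bad.sum())
        fv_vals = np.where(bad, 0.0, amps[:, 0] / np.where(bad, 1.0, means))
        fv[s][sel] = fv_vals
        q[s][sel] = amps[:, 1]
    if n_bad:
        logger.warning("%d lung voxels with non-positive mean signal; fv=0",
                       n_bad)
    return FunctionalMaps(fv=fv, q=q, f_resp=freqs.f_resp,
                          f_card=freqs.f_card)


def defect_mask(values: np.ndarray, mask: LungMask,
                threshold_factor: float = THRESHOLD_FACTOR) -> np.ndarray:
    """Slice-wise relative-median defect rule (one channel).

    A lung voxel is defective iff its value is strictly below
    ``threshold_factor`` times the median over the lung voxels of its own
    slice (median of an even count = mean of the central pair; slices with
    no lung voxels contribute nothing).
    """
    if not (0.0 < threshold_factor <= 1.0):
        raise ConfigurationError(
            f"threshold_factor={threshold_factor} must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    lung = mask.lung
    if values.shape != lung.shape:
        raise ConfigurationError("values grid does not match the mask")
    out = np.zeros(lung.shape, dtype=bool)
    for s in range(lung.shape[0]):
        sel = lung[s]
        if not sel.any():
            continue
        med = np.median(values[s][sel])
        out[s] = sel & (values[s] < threshold_factor * med)
    return out


def compute_defect_masks(maps: FunctionalMaps, mask: LungMask,
                         threshold_factor: float = THRESHOLD_FACTOR
                         ) -> DefectMasks:
    """Apply the defect rule to both channels of a map set."""
    return DefectMasks(
        v_defect=defect_mask(maps.fv, mask, threshold_factor),
        q_defect=defect_mask(maps.q, mask, threshold_factor),
        threshold_factor=threshold_factor,
    )
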