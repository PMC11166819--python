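"""Pipeline orchestration: per-subject analysis and cohort statistics.

``run_subject`` chains preprocess -> spectral -> maps -> metrics on one
series, writing maps, defect masks, a metrics row and a provenance
manifest.  ``run_cohort`` reproduces the cohort analysis design on a
metrics table (raw per-subject rows) or on published group summaries
(summary mode).  All outputs carry the configuration hash so mixed-config
cohorts can be detected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    GROUPS,
    LUNG_FUNCTION_OUTCOMES,
    POSTHOC_METHOD,
    SIDE_OUTCOMES,
    bonferroni_side_posthoc,
    mixed_anova_group_side,
    one_way_anova,
    posthoc_table,
    spearman_bh,
    summarize,
)
from .defect_metrics import DDI_RADIUS, compute_defect_metrics
from .errors import ConfigurationError, SchemaError
from .funcmaps import (
    THRESHOLD_FACTOR,
    VOXEL_ORDER,
    compute_defect_masks,
    compute_functional_maps,
)
from .io import read_mask, read_series, write_mask, write_series
from .mp_spectral import (
    CARD_BAND,
    MATCH_TOL_HZ,
    RESP_BAND,
    SV_THRESHOLD,
    estimate_cardinal_frequencies,
)
from .preprocess import (
    LungMask,
    register_translation,
    segment_lungs_fallback,
    select_baseline_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the per-subject pipeline; round-trips via JSON."""

    threshold_factor: float = THRESHOLD_FACTOR
    resp_band: tuple[float, float] = RESP_BAND
    card_band: tuple[float, float] = CARD_BAND
    pencil_order: int = VOXEL_ORDER
    sv_threshold: float = SV_THRESHOLD
    match_tol_hz: float = MATCH_TOL_HZ
    ddi_radius: float = DDI_RADIUS
    registration: bool = True
    allow_fallback_segmentation: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        cfg = cls(**raw)
        cfg.resp_band = tuple(cfg.resp_band)
        cfg.card_band = tuple(cfg.card_band)
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def metrics_row(metrics, subject_id: str, group: str,
                hernia_side: str | None, config_hash: str) -> dict:
    """Flatten a DefectMetrics into one cohort-table row."""
    row = {
        "subject_id": subject_id, "group": group,
        "hernia_side": hernia_side or "none",
        "vdp_pct": metrics.vdp, "qdp_pct": metrics.qdp,
        "vqd_pct": metrics.vqd_match,
        "ddi_v": metrics.ddi_v, "ddi_q": metrics.ddi_q,
        "config_hash": config_hash,
    }
    for key, val in metrics.vdp_side.items():
        row[f"vdp_pct_{key}"] = val
    for key, val in metrics.qdp_side.items():
        row[f"qdp_pct_{key}"] = val
    for key, val in metrics.vqd_side.items():
        row[f"vqd_pct_{key}"] = val
    for key, val in metrics.ddi_v_side.items():
        row[f"ddi_v_{key}"] = val
    for key, val in metrics.ddi_q_side.items():
        row[f"ddi_q_{key}"] = val
    row.update({f"n_{k}": v for k, v in metrics.counts.items()})
    return row


def analyze_series(series, mask, config: PipelineConfig,
                   hernia_side: str | None = None):
    """In-memory per-subject pipeline; returns (metrics, maps, masks)."""
    t0 = time.perf_counter()
    if config.registration and not series.registered:
        baseline = select_baseline_frame(series, mask)
        series = register_translation(series, baseline)
        logger.info("registered to baseline frame %d (%.1f s)", baseline,
                    time.perf_counter() - t0)
    elif not series.registered:
        # spectral amplitude extraction assumes voxel correspondence
        series = series.__class__(data=series.data,
                                  frame_rate=series.frame_rate,
                                  voxel_size=series.voxel_size,
                                  registered=True,
                                  shifts=np.zeros((series.n_slices,
                                                   series.n_frames, 2)))
        logger.warning("registration disabled; treating series as aligned")
    freqs = estimate_cardinal_frequencies(
        series, mask, resp_band=config.resp_band, card_band=config.card_band,
        sv_threshold=config.sv_threshold)
    maps = compute_functional_maps(series, mask, freqs,
                                   order=config.pencil_order,
                                   tol=config.match_tol_hz)
    masks = compute_defect_masks(maps, mask, config.threshold_factor)
    metrics = compute_defect_metrics(masks.v_defect, masks.q_defect, mask,
                                     hernia_side=hernia_side,
                                     ddi_radius=config.ddi_radius)
    logger.info("subject analyzed in %.1f s", time.perf_counter() - t0)
    return metrics, maps, masks


def run_subject(series_path: str | Path, mask_path: str | Path | None,
                meta_path: str | Path | None, config: PipelineConfig,
                out_dir: str | Path) -> dict:
    """File-level per-subject pipeline; writes maps, metrics and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = read_series(series_path)
    if mask_path is not None and Path(mask_path).exists():
        mask = read_mask(mask_path)
    elif config.allow_fallback_segmentation:
        logger.warning("no mask supplied; using fallback segmentation")
        mask = segment_lungs_fallback(series.data.mean(axis=1))
    else:
        raise ConfigurationError(
            f"mask {mask_path!r} not found and fallback segmentation is "
            "disabled")
    if mask.labels.shape != (series.n_slices, *series.grid):
        raise ConfigurationError(
            f"mask grid {mask.labels.shape} does not match series grid "
            f"{(series.n_slices, *series.grid)}")
    meta = {"subject_id": Path(series_path).name.split(".")[0],
            "group": "unknown", "hernia_side": None}
    if meta_path is not None:
        meta.update(json.loads(Path(meta_path).read_text()))

    metrics, maps, masks = analyze_series(series, mask, config,
                                          hernia_side=meta["hernia_side"])

    import nibabel as nib  # local: only the file layer touches nibabel
    aff = np.diag([*series.voxel_size, 1.0])

    def _save(arr, name, dtype=np.float32):
        nib.save(nib.Nifti1Image(
            np.transpose(arr, (1, 2, 0)).astype(dtype), aff), out_dir / name)

    _save(maps.fv, "fv_map.nii.gz")
    _save(maps.q, "q_map.nii.gz")
    _save(masks.v_defect.astype(np.uint8)
          + 2 * masks.q_defect.astype(np.uint8), "defect_masks.nii.gz",
          np.uint8)
    row = metrics_row(metrics, meta["subject_id"], meta["group"],
                      meta["hernia_side"], config.config_hash)
    pd.DataFrame([row]).to_csv(out_dir / "metrics.csv", index=False)
    manifest = {
        "software": f"mplung {__version__}",
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "f_resp_hz": maps.f_resp, "f_card_hz": maps.f_card,
        "inputs": {"series": str(series_path), "mask": str(mask_path),
                   "meta": str(meta_path)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "metrics.json").write_text(json.dumps(row, indent=2))
    return row


def _check_single_config(table: pd.DataFrame) -> None:
    if "config_hash" in table.columns:
        hashes = set(table["config_hash"].dropna().astype(str))
        if len(hashes) > 1:
            raise SchemaError(
                f"refusing to mix configurations in one cohort: {hashes}")


def cohort_results(table: pd.DataFrame,
                   outcomes: list[str] | None = None,
                   methods: dict[str, str] | None = None) -> dict:
    """Full raw-mode cohort analysis on a per-subject table.

    Returns a dict with ``anova`` (one-way, per outcome), ``posthoc``
    (pairwise contrasts per outcome), ``mixed`` and ``side_posthoc``
    (side-specific imaging outcomes), and ``spearman`` matrices.
    """
    if "group" not in table.columns:
        raise SchemaError("cohort table needs a 'group' column")
    groups = [g for g in table["group"].unique()]
    if len(groups) < 2:
        raise SchemaError("between-group analysis needs at least 2 groups; "
                          f"got {groups}")
    _check_single_config(table)
    methods = {**POSTHOC_METHOD, **(methods or {})}
    if outcomes is None:
        outcomes = [o for o in POSTHOC_METHOD if o in table.columns]
    results: dict = {"anova": {}, "posthoc": {}, "mixed": {},
                     "side_posthoc": {}}
    for o in outcomes:
        summary = summarize(table, o)
        summary = {g: v for g, v in summary.items() if v[2] >= 2}
        if len(summary) < 2:
            continue
        results["anova"][o] = one_way_anova(summary)
        results["posthoc"][o] = posthoc_table(
            summary, methods.get(o, "tukey_kramer"))
    for o in SIDE_OUTCOMES:
        if f"{o}_affected" not in table.columns:
            continue
        try:
            results["mixed"][o] = mixed_anova_group_side(table, o)
            results["side_posthoc"][o] = bonferroni_side_posthoc(table, o)
        except SchemaError as exc:
            logger.warning("side analysis of %s skipped: %s", o, exc)
    lung_fn = [o for o in LUNG_FUNCTION_OUTCOMES if o in table.columns]
    mri_aff = [f"{o}_affected" for o in SIDE_OUTCOMES
               if f"{o}_affected" in table.columns]
    if lung_fn and mri_aff:
        cdh = table[table["group"] != "control"]
        if len(cdh) >= 4:
            results["spearman"] = spearman_bh(cdh, lung_fn, mri_aff)
    return results


def run_cohort(table_path: str | Path, out_dir: str | Path,
               summary_mode: bool = False) -> dict:
    """File-level cohort stage: CSV in, result CSVs + JSON report out."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(table_path)
    if summary_mode:
        required = {"group", "outcome", "mean", "sd", "n"}
        if not required.issubset(table.columns):
            raise SchemaError(
                f"summary table must have columns {sorted(required)}; "
                f"missing {sorted(required - set(table.columns))}")
        report_rows = []
        for o, sub in table.groupby("outcome", sort=False):
            summary = {str(r.group): (float(r.mean), float(r.sd), int(r.n))
                       for r in sub.itertuples()}
            method = POSTHOC_METHOD.get(str(o), "tukey_kramer")
            for res in posthoc_table(summary, method):
                report_rows.append({
                    "outcome": o, "group_1": res.pair[0],
                    "group_2": res.pair[1],
                    "mean_difference": res.mean_difference,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_adjusted": res.p_adjusted, "method": res.method,
                })
        df = pd.DataFrame(report_rows)
        df.to_csv(out_dir / "posthoc_summary_mode.csv", index=False)
        return {"posthoc": df}

    results = cohort_results(table)
    posthoc_rows = [
        {"outcome": o, "group_1": r.pair[0], "group_2": r.pair[1],
         "mean_difference": r.mean_difference, "ci_low": r.ci_low,
         "ci_high": r.ci_high, "p_adjusted": r.p_adjusted, "method": r.method}
        for o, rs in results["posthoc"].items() for r in rs
    ]
    pd.DataFrame(posthoc_rows).to_csv(out_dir / "group_posthoc.csv",
                                      index=False)
    side_rows = [
        {"outcome": o, "group": g, "mean_difference": r.mean_difference,
         "ci_low": r.ci_low, "ci_high": r.ci_high,
         "p_adjusted": r.p_adjusted}
        for o, per_group in results["side_posthoc"].items()
        for g, r in per_group.items()
    ]
    pd.DataFrame(side_rows).to_csv(out_dir / "side_posthoc.csv", index=False)
    report = {
        "anova": results["anova"],
        "mixed": results["mixed"],
    }
    (out_dir / "cohort_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    if "spearman" in results:
        rho, padj = results["spearman"]
        rho.to_csv(out_dir / "spearman_rho.csv")
        padj.to_csv(out_dir / "spearman_p_adjusted.csv")
    return results
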