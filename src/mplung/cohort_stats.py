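"""Group-level statistics for lung-function and functional-MRI outcomes.

The analysis design mirrors a three-group CDH cohort study (healthy
controls, small CDH repaired primarily, large CDH needing patch/flap
repair): one-way ANOVA with Tukey-Kramer / Games-Howell / BH-adjusted
post-hoc contrasts on whole-lung outcomes, a two-way mixed (group x lung
side) repeated-measures ANOVA with Bonferroni-adjusted paired contrasts on
side-specific outcomes, and BH-adjusted Spearman correlations between lung
function and imaging.

Two input modes are supported everywhere it is meaningful:

* **raw mode** — a per-subject table (one row per subject);
* **summary mode** — published group summaries (mean, SD, n per group),
  enough for post-hoc mean differences and Tukey/Games-Howell intervals.

``CDH_COHORT_SUMMARIES`` and ``CDH_SIDE_SUMMARIES`` ship the published
group summaries of the reference cohort (13 controls / 7 small CDH /
6 large CDH) as worked-example inputs and as defaults for the synthetic
cohort generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

GROUPS = ("control", "small_CDH", "large_CDH")
ALPHA = 0.05

#: whole-lung outcomes: {outcome: {group: (mean, sd, n)}}
CDH_COHORT_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "fev1_z": {"control": (0.40, 0.93, 13), "small_CDH": (-0.33, 1.04, 7),
               "large_CDH": (-3.86, 1.43, 6)},
    "fvc_z": {"control": (0.43, 0.80, 13), "small_CDH": (-0.51, 1.29, 7),
              "large_CDH": (-3.54, 2.30, 6)},
    "fev1_fvc_pct": {"control": (87.26, 5.67, 13),
                     "small_CDH": (89.25, 5.45, 7),
                     "large_CDH": (77.25, 11.39, 6)},
    "tlc_z": {"control": (0.62, 0.87, 13), "small_CDH": (-0.61, 1.21, 6),
              "large_CDH": (-0.96, 0.87, 6)},
    "rv_tlc_pct": {"control": (27.81, 6.58, 13),
                   "small_CDH": (28.38, 4.36, 6),
                   "large_CDH": (45.82, 5.36, 6)},
    "lci2_5_TO": {"control": (6.17, 0.35, 13), "small_CDH": (6.71, 0.49, 6),
                  "large_CDH": (7.29, 0.76, 5)},
    "vdp_pct": {"control": (15.53, 4.55, 13), "small_CDH": (15.03, 1.49, 7),
                "large_CDH": (24.12, 3.46, 6)},
    "qdp_pct": {"control": (14.53, 2.91, 13), "small_CDH": (14.41, 4.17, 7),
                "large_CDH": (31.75, 2.88, 6)},
    "ddi_v": {"control": (1.06, 0.62, 13), "small_CDH": (1.53, 1.38, 7),
              "large_CDH": (2.51, 0.48, 6)},
    "ddi_q": {"control": (0.82, 0.50, 13), "small_CDH": (1.58, 1.92, 7),
              "large_CDH": (5.49, 1.58, 6)},
    "vqd_pct": {"control": (2.05, 1.89, 13), "small_CDH": (2.31, 2.39, 7),
                "large_CDH": (12.02, 3.24, 6)},
}

#: side-specific imaging outcomes:
#: {outcome: {group: {"non_affected"|"affected": (mean, sd)}}}; n as above
CDH_SIDE_SUMMARIES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "vdp_pct": {
        "control": {"non_affected": (8.62, 2.67), "affected": (6.91, 2.52)},
        "small_CDH": {"non_affected": (6.65, 2.39), "affected": (8.38, 2.42)},
        "large_CDH": {"non_affected": (4.68, 2.08), "affected": (19.44, 2.45)},
    },
    "qdp_pct": {
        "control": {"non_affected": (6.79, 2.45), "affected": (7.74, 1.18)},
        "small_CDH": {"non_affected": (4.75, 1.76), "affected": (9.66, 5.03)},
        "large_CDH": {"non_affected": (4.13, 6.60), "affected": (27.61, 8.60)},
    },
    "ddi_v": {
        "control": {"non_affected": (1.57, 0.78), "affected": (2.60, 2.12)},
        "small_CDH": {"non_affected": (1.20, 0.40), "affected": (3.92, 3.63)},
        "large_CDH": {"non_affected": (2.06, 2.39), "affected": (5.07, 1.71)},
    },
    "ddi_q": {
        "control": {"non_affected": (1.06, 0.69), "affected": (2.14, 1.40)},
        "small_CDH": {"non_affected": (1.01, 0.52), "affected": (3.53, 3.91)},
        "large_CDH": {"non_affected": (2.72, 5.09), "affected": (9.59, 5.13)},
    },
    "vqd_pct": {
        "control": {"non_affected": (1.72, 1.83), "affected": (2.45, 2.44)},
        "small_CDH": {"non_affected": (0.70, 0.43), "affected": (4.22, 5.34)},
        "large_CDH": {"non_affected": (1.18, 1.20), "affected": (22.11, 7.71)},
    },
}

#: default post-hoc method per whole-lung outcome
POSTHOC_METHOD: dict[str, str] = {
    "fev1_z": "tukey_kramer",
    "fvc_z": "tukey_kramer",
    "fev1_fvc_pct": "games_howell",
    "tlc_z": "tukey_kramer",
    "rv_tlc_pct": "tukey_kramer",
    "lci2_5_TO": "tukey_kramer",
    "vdp_pct": "games_howell",
    "qdp_pct": "tukey_kramer",
    "ddi_v": "bh",
    "ddi_q": "bh",
    "vqd_pct": "tukey_kramer",
}

SIDE_OUTCOMES = ("vdp_pct", "qdp_pct", "ddi_v", "ddi_q", "vqd_pct")
LUNG_FUNCTION_OUTCOMES = ("fev1_z", "fvc_z", "fev1_fvc_pct", "tlc_z",
                          "rv_tlc_pct", "lci2_5_TO")

SummaryDict = dict[str, tuple[float, float, int]]


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    mean_difference: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ConfigurationError("CI does not bracket the mean difference")


def _validate_summary(summary: SummaryDict) -> None:
    for g, (_, sd, n) in summary.items():
        if n < 2:
            raise SchemaError(f"group {g!r} has n={n} < 2")
        if sd < 0:
            raise SchemaError(f"group {g!r} has sd={sd} < 0")


def summarize(table: pd.DataFrame, outcome: str,
              group_col: str = "group") -> SummaryDict:
    """Per-group (mean, sd, n) with per-outcome complete cases."""
    if outcome not in table.columns:
        raise SchemaError(f"missing outcome column {outcome!r}")
    out: SummaryDict = {}
    for g, sub in table.groupby(group_col, sort=False):
        vals = sub[outcome].dropna().to_numpy(dtype=float)
        if len(vals) >= 1:
            out[str(g)] = (float(vals.mean()),
                           float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                           int(len(vals)))
    return out


def one_way_anova(data: pd.DataFrame | SummaryDict,
                  outcome: str | None = None) -> dict:
    """Between-group F test from raw values or from group summaries.

    Summary mode uses the pooled within-group sum of squares, which is
    algebraically identical to the raw-data F.
    """
    if isinstance(data, pd.DataFrame):
        if outcome is None:
            raise ConfigurationError("outcome required with a raw table")
        groups = [sub[outcome].dropna().to_numpy(dtype=float)
                  for _, sub in data.groupby("group", sort=False)]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2:
            raise SchemaError("need at least 2 groups")
        if any(len(g) < 2 for g in groups):
            raise SchemaError("every group needs n >= 2")
        f, p = stats.f_oneway(*groups)
        k, n_tot = len(groups), sum(len(g) for g in groups)
        return {"F": float(f), "df": (k - 1, n_tot - k), "p": float(p)}

    summary = data
    _validate_summary(summary)
    if len(summary) < 2:
        raise SchemaError("need at least 2 groups")
    means = np.array([summary[g][0] for g in summary])
    sds = np.array([summary[g][1] for g in summary])
    ns = np.array([summary[g][2] for g in summary])
    k, n_tot = len(means), int(ns.sum())
    grand = float((ns * means).sum() / n_tot)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, n_tot - k
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
    return {"F": float(f), "df": (df1, df2),
            "p": float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0}


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    denom = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    if denom == 0:
        return float(n1 + n2 - 2)
    return float((v1 + v2) ** 2 / denom)


def posthoc_from_summary(summary: SummaryDict, pair: tuple[str, str],
                         method: str, alpha: float = ALPHA) -> PosthocResult:
    """One pairwise contrast from group summaries.

    ``mean_difference`` is mean(pair[1]) - mean(pair[0]).  Methods:

    * ``tukey_kramer`` — studentized-range CI/p with the within-group MSE
      pooled over *all* groups in ``summary`` (df = N - k);
    * ``games_howell`` — per-pair variances, Welch df, studentized-range
      quantile (robust to unequal variances);
    * ``bonferroni`` — Welch t with p and CI adjusted for all pairs;
    * ``bh`` — Welch t, p Benjamini-Hochberg-adjusted across all pairwise
      contrasts of this summary; the CI is the unadjusted Welch interval.
    """
    _validate_summary(summary)
    g1, g2 = pair
    for g in pair:
        if g not in summary:
            raise SchemaError(f"group {g!r} not in summary")
    m1, s1, n1 = summary[g1]
    m2, s2, n2 = summary[g2]
    diff = m2 - m1
    k = len(summary)
    n_pairs = k * (k - 1) // 2

    if method == "tukey_kramer":
        ns = np.array([summary[g][2] for g in summary])
        sds = np.array([summary[g][1] for g in summary])
        df = int(ns.sum()) - k
        mse = float(((ns - 1) * sds**2).sum() / df)
        se = np.sqrt(mse / 2 * (1 / n1 + 1 / n2))
        qcrit = stats.studentized_range.ppf(1 - alpha, k, df)
        p = float(stats.studentized_range.sf(abs(diff) / se, k, df)) if se > 0 \
            else (1.0 if diff == 0 else 0.0)
        half = qcrit * se
    elif method == "games_howell":
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
        df = _welch_df(s1, n1, s2, n2)
        qcrit = stats.studentized_range.ppf(1 - alpha, k, df)
        p = float(stats.studentized_range.sf(abs(diff) * np.sqrt(2) / se,
                                             k, df)) if se > 0 \
            else (1.0 if diff == 0 else 0.0)
        half = qcrit * se / np.sqrt(2)
    elif method in ("bonferroni", "bh"):
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
        df = _welch_df(s1, n1, s2, n2)
        if se > 0:
            p_raw = float(2 * stats.t.sf(abs(diff) / se, df))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        if method == "bonferroni":
            p = min(1.0, n_pairs * p_raw)
            tcrit = stats.t.ppf(1 - alpha / (2 * n_pairs), df)
        else:
            p_all = {}
            for a, b in combinations(summary, 2):
                ma, sa, na = summary[a]
                mb, sb, nb = summary[b]
                se_ab = np.sqrt(sa**2 / na + sb**2 / nb)
                df_ab = _welch_df(sa, na, sb, nb)
                p_all[(a, b)] = (
                    float(2 * stats.t.sf(abs(mb - ma) / se_ab, df_ab))
                    if se_ab > 0 else (1.0 if mb == ma else 0.0)
                )
            keys = list(p_all)
            adj = bh_adjust(np.array([p_all[key] for key in keys]))
            lookup = dict(zip(keys, adj))
            p = float(lookup.get((g1, g2), lookup.get((g2, g1))))
            tcrit = stats.t.ppf(1 - alpha / 2, df)
        half = tcrit * se
    else:
        raise ConfigurationError(f"unknown post-hoc method {method!r}")

    return PosthocResult(pair=(g1, g2), mean_difference=float(diff),
                         ci_low=float(diff - half), ci_high=float(diff + half),
                         p_adjusted=float(min(1.0, max(0.0, p))),
                         method=method)


def posthoc_table(summary: SummaryDict, method: str,
                  alpha: float = ALPHA) -> list[PosthocResult]:
    """All pairwise contrasts of a summary, in group order."""
    return [posthoc_from_summary(summary, (a, b), method, alpha)
            for a, b in combinations(summary, 2)]


def _side_long(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    aff, non = f"{outcome}_affected", f"{outcome}_non_affected"
    for col in (aff, non, "group", "subject_id"):
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    wide = table[["subject_id", "group", non, aff]].dropna()
    n_dropped = len(table) - len(wide)
    if n_dropped:
        logger.warning("%s: dropped %d subjects missing a side value",
                       outcome, n_dropped)
    long = wide.melt(id_vars=["subject_id", "group"],
                     value_vars=[non, aff], var_name="side",
                     value_name="value")
    long["side"] = np.where(long["side"] == aff, "affected", "non_affected")
    return long


def mixed_anova_group_side(table: pd.DataFrame, outcome: str) -> dict:
    """Two-way mixed ANOVA: between = group, within = lung side.

    Subjects missing either side value are dropped (logged).  Returns a
    dict with ``group``, ``side`` and ``interaction`` effects, each a dict
    of F, df (pair) and p.
    """
    import pingouin as pg  # deferred: pingouin pulls in matplotlib

    long = _side_long(table, outcome)
    counts = long.groupby("group")["subject_id"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise SchemaError(
            f"need >=2 complete subjects in >=2 groups; got {counts.to_dict()}"
        )
    aov = pg.mixed_anova(data=long, dv="value", within="side",
                         subject="subject_id", between="group")
    aov = aov.set_index("Source")
    out = {}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    ss_scale = float(np.abs(aov["SS"]).sum())
    for key, src in (("group", "group"), ("side", "side"),
                     ("interaction", "Interaction")):
        row = aov.loc[src]
        f_val = float(row["F"])
        p_val = float(row[p_col])
        if float(row["SS"]) <= 1e-9 * max(ss_scale, 1e-300):
            # degenerate effect (e.g. identical sides): SS is numerical
            # zero and F is 0/0 noise
            f_val, p_val = 0.0, 1.0
        out[key] = {"F": f_val,
                    "df": (float(row["DF1"]), float(row["DF2"])),
                    "p": p_val}
    return out


def bonferroni_side_posthoc(table: pd.DataFrame, outcome: str,
                            alpha: float = ALPHA) -> dict[str, PosthocResult]:
    """Per-group paired contrast (affected - non-affected), Bonferroni over
    groups; groups with fewer than 2 complete pairs are skipped with a
    warning."""
    aff, non = f"{outcome}_affected", f"{outcome}_non_affected"
    diffs: dict[str, np.ndarray] = {}
    for g, sub in table.groupby("group", sort=False):
        d = (sub[aff] - sub[non]).dropna().to_numpy(dtype=float)
        if len(d) < 2:
            logger.warning("%s/%s: <2 complete pairs, group skipped",
                           outcome, g)
            continue
        diffs[str(g)] = d
    if not diffs:
        raise SchemaError(f"{outcome}: no group has 2 complete pairs")
    k = len(diffs)
    results = {}
    for g, d in diffs.items():
        n = len(d)
        mean_d = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if se == 0:
            p_raw = 1.0 if mean_d == 0 else 0.0
            half = 0.0
        else:
            p_raw = float(2 * stats.t.sf(abs(mean_d) / se, n - 1))
            half = float(stats.t.ppf(1 - alpha / (2 * k), n - 1) * se)
        results[g] = PosthocResult(
            pair=("non_affected", "affected"), mean_difference=mean_d,
            ci_low=mean_d - half, ci_high=mean_d + half,
            p_adjusted=min(1.0, k * p_raw), method="bonferroni",
        )
    return results


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def spearman_bh(table: pd.DataFrame, x_outcomes: list[str],
                y_outcomes: list[str], min_n: int = 4
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho for every (x, y) pair with BH adjustment over the full
    matrix of tests.  Cells with <``min_n`` complete pairs or a constant
    column are reported as NaN with a warning."""
    rho = pd.DataFrame(index=x_outcomes, columns=y_outcomes, dtype=float)
    praw = pd.DataFrame(index=x_outcomes, columns=y_outcomes, dtype=float)
    for x in x_outcomes:
        for y in y_outcomes:
            sub = table[[x, y]].dropna()
            if len(sub) < min_n:
                logger.warning("spearman %s~%s: only %d complete pairs",
                               x, y, len(sub))
                continue
            if sub[x].nunique() < 2 or sub[y].nunique() < 2:
                logger.warning("spearman %s~%s: constant column", x, y)
                continue
            r, p = stats.spearmanr(sub[x], sub[y])
            rho.loc[x, y], praw.loc[x, y] = float(r), float(p)
    padj = praw.copy()
    flat = praw.to_numpy().ravel()
    ok = np.isfinite(flat)
    if ok.any():
        flat[ok] = bh_adjust(flat[ok])
        padj.loc[:, :] = flat.reshape(praw.shape)
    return rho, padj
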