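"""Group comparison and brain-behavior statistics.

The statistical layer of the pipeline: demographic/clinical two-sample
tests (Welch or pooled Student t, chi-square on 2x2 tables,
Mann-Whitney U), label-shuffling permutation tests to confirm parametric
results, Bonferroni-corrected nodal comparisons, and Pearson/partial
correlations between network AUC summaries and clinical scores in the
patient group.

t-tests accept either raw samples or printed summary triples
(mean, sd, n), so group rows published in a demographics table can be
re-derived directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import GLOBAL_METRICS, NODAL_METRICS, MetricProfile

__all__ = [
    "SummaryStats",
    "StatResult",
    "StatsConfig",
    "ComparisonTable",
    "two_sample_t",
    "chi_square_2x2",
    "mann_whitney_u",
    "permutation_two_sample",
    "pearson_correlation",
    "partial_correlation",
    "bonferroni_levels",
    "compare_groups",
]

#: clinical scores examined in brain-behavior correlations
CLINICAL_SCORES = ("abc_spontaneous", "abc_auditory", "abc_repetition",
                   "abc_naming", "language_ability", "mmse", "moca")


class SummaryStats(NamedTuple):
    """Printed summary triple for one group: mean, sd, n."""

    mean: float
    sd: float
    n: int


class BonferroniLevels(NamedTuple):
    """Per-test alpha levels: strict = alpha/m, liberal = 1/m."""

    strict: float
    liberal: float


@dataclass(frozen=True)
class StatResult:
    """One test or correlation outcome."""

    method: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n: tuple | int | None = None
    correction: str = "none"
    alpha_effective: float | None = None

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p-value out of [0, 1]")


def _as_summary(x) -> SummaryStats:
    # raw samples are reduced to their triple; a length-3 sequence is
    # still a sample — printed triples must be passed as SummaryStats
    if isinstance(x, SummaryStats):
        return x
    arr = np.asarray(x, dtype=float)
    return SummaryStats(float(arr.mean()), float(arr.std(ddof=1)),
                        int(arr.size))


def two_sample_t(a, b, variant: str = "welch") -> StatResult:
    """Two-sample t-test from raw samples or ``SummaryStats`` triples.

    ``variant='welch'`` uses unequal variances with Satterthwaite df;
    ``variant='student'`` pools the variance with df = n_a + n_b - 2.
    Two-sided p.
    """
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    sa, sb = _as_summary(a), _as_summary(b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("each group needs n >= 2")
    if sa.sd < 0 or sb.sd < 0:
        raise ValueError("sd must be non-negative")
    va, vb = sa.sd ** 2, sb.sd ** 2
    diff = sa.mean - sb.mean
    if variant == "welch":
        se2 = va / sa.n + vb / sb.n
        if se2 == 0:
            if diff == 0:
                raise ValueError("zero variance in both groups with equal "
                                 "means: t undefined")
            t = math.inf if diff > 0 else -math.inf
            df = sa.n + sb.n - 2
        else:
            t = diff / math.sqrt(se2)
            df = se2 ** 2 / ((va / sa.n) ** 2 / (sa.n - 1)
                             + (vb / sb.n) ** 2 / (sb.n - 1))
    else:
        sp2 = ((sa.n - 1) * va + (sb.n - 1) * vb) / (sa.n + sb.n - 2)
        df = sa.n + sb.n - 2
        if sp2 == 0:
            if diff == 0:
                raise ValueError("zero variance in both groups with equal "
                                 "means: t undefined")
            t = math.inf if diff > 0 else -math.inf
        else:
            t = diff / math.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    p = float(2 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return StatResult(method=f"{variant}_t", statistic=float(t),
                      p_value=p, df=float(df), n=(sa.n, sb.n))


def chi_square_2x2(counts, yates: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    ``yates=True`` applies the continuity correction
    (|O - E| reduced by 0.5 before squaring).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, 1))
    return StatResult(method="chi_square", statistic=stat, p_value=p,
                      df=1.0, n=int(total))


def mann_whitney_u(a, b) -> StatResult:
    """Mann-Whitney U (U reported for sample ``a``).

    Exact-enumeration p when n_a + n_b <= 12 and the data are tie-free,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([a, b])
    small = a.size + b.size <= 12
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(method="mann_whitney_u",
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(a.size, b.size))


def _welch_t_only(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    diff = a.mean() - b.mean()
    if se2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(se2)


def permutation_two_sample(a, b, n_perm: int = 5000,
                           seed: int = 0) -> StatResult:
    """Group-label shuffling test on the Welch t statistic, two-sided.

    Exhaustive enumeration replaces sampling whenever the number of
    distinct relabelings C(n_a + n_b, n_a) is at most 10,000; sampled p
    uses the add-one estimator (1 + hits) / (n_perm + 1) and so never
    reaches 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = _welch_t_only(a, b)
    if math.isnan(t_obs):
        raise ValueError("degenerate samples: observed t undefined")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    eps = 1e-12
    if math.comb(n, na) <= 10_000:
        hits = 0
        total = 0
        idx_all = set(range(n))
        for idx in combinations(range(n), na):
            sel = np.fromiter(idx, dtype=int)
            rest = np.fromiter(sorted(idx_all - set(idx)), dtype=int)
            t = _welch_t_only(pooled[sel], pooled[rest])
            if abs(t) >= abs(t_obs) - eps:
                hits += 1
            total += 1
        p = hits / total
        method = "permutation_t_exact"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            t = _welch_t_only(pooled[perm[:na]], pooled[perm[na:]])
            if abs(t) >= abs(t_obs) - eps:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        method = "permutation_t"
    return StatResult(method=method, statistic=float(t_obs), p_value=p,
                      n=(a.size, b.size))


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(method="pearson_r", statistic=float(res.statistic),
                      p_value=float(res.pvalue), df=float(x.size - 2),
                      n=int(x.size))


def partial_correlation(x, y, covariates) -> StatResult:
    """Correlation of x and y after regressing out the covariates.

    Both variables are projected onto [intercept + covariates] by least
    squares and the Pearson correlation of the residuals is tested with
    df = n - 2 - n_covariates.  An empty covariate set reduces exactly
    to ``pearson_correlation``.  Sex-like string columns must be encoded
    0/1 by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.size == 0:
        cov = np.empty((x.size, 0))
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must share n")
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) == 1.0:
        p = 0.0
    else:
        t = r_c * math.sqrt(df / (1 - r_c ** 2))
        p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(method="partial_r", statistic=r, p_value=p,
                      df=float(df), n=int(n))


def bonferroni_levels(alpha: float, m: int) -> BonferroniLevels:
    """Strict alpha/m family-wise level plus the liberal exploratory
    1/m level."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return BonferroniLevels(strict=alpha / m, liberal=1.0 / m)


# ---------------------------------------------------------------------------
# Cohort-level comparison


@dataclass(frozen=True)
class StatsConfig:
    t_variant: str = "welch"
    n_perm: int = 5000
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "head_motion", "duration")
    seed: int = 0
    run_nodal: bool = True
    run_behavior: bool = True


@dataclass(frozen=True)
class ComparisonTable:
    """Group-difference and brain-behavior results for one cohort.

    ``global_tests``: one row per global AUC metric with parametric,
    Mann-Whitney and permutation p-values.  ``nodal_tests``: one row per
    node x metric with Bonferroni flags at the strict (alpha/N) and
    liberal (1/N) levels.  ``behavior``: Pearson and partial
    correlations, patient group only, for metrics significant globally.
    """

    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    behavior: pd.DataFrame
    alpha: float
    bonferroni: BonferroniLevels | None = None


def _auc_matrix(profiles: Sequence[MetricProfile], metric: str,
                nodal: bool):
    if nodal:
        return np.stack([p.auc_nodal[metric].to_numpy() for p in profiles])
    return np.array([p.auc_global[metric] for p in profiles])


def compare_groups(profiles: Sequence[MetricProfile],
                   clinical: pd.DataFrame,
                   config: StatsConfig | None = None) -> ComparisonTable:
    """Run the full statistical layer on per-subject metric profiles.

    Global AUCs are compared patient-vs-control at the uncorrected alpha
    with a t-test (Welch by default), a Mann-Whitney U and a label-
    shuffling permutation test; nodal AUCs (DC, BC, NEg, NEloc per node)
    with t-tests flagged at both Bonferroni levels; clinical
    correlations are computed within the patient group for every global
    metric that reached significance.
    """
    config = config or StatsConfig()
    clin = clinical.set_index("subject_id")
    ids = [p.subject_id for p in profiles]
    missing = [i for i in ids if i not in clin.index]
    if missing:
        raise ValueError(f"clinical table lacks subjects: {missing}")
    group = clin.loc[ids, "group"].to_numpy()
    pat = group == "patient"
    con = group == "control"
    if pat.sum() < 2 or con.sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    metrics_avail = [m for m in GLOBAL_METRICS
                     if all(m in p.auc_global.index for p in profiles)]
    rows = []
    for j, m in enumerate(metrics_avail):
        v = _auc_matrix(profiles, m, nodal=False)
        a, b = v[pat], v[con]
        t_res = two_sample_t(a, b, variant=config.t_variant)
        u_res = mann_whitney_u(a, b)
        p_res = permutation_two_sample(a, b, n_perm=config.n_perm,
                                       seed=config.seed + j)
        rows.append({
            "metric": m,
            "mean_patient": float(a.mean()), "mean_control": float(b.mean()),
            "t": t_res.statistic, "df": t_res.df, "p_t": t_res.p_value,
            "U": u_res.statistic, "p_u": u_res.p_value,
            "p_perm": p_res.p_value,
            "significant": t_res.p_value < config.alpha,
        })
    global_df = pd.DataFrame(rows)

    n_nodes = profiles[0].auc_nodal.shape[0]
    levels = bonferroni_levels(config.alpha, n_nodes)
    nodal_rows = []
    if config.run_nodal:
        for m in NODAL_METRICS:
            v = _auc_matrix(profiles, m, nodal=True)
            for node in range(n_nodes):
                col = v[:, node]
                a, b = col[pat], col[con]
                if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 \
                        and a.mean() == b.mean():
                    t_val, p_val = 0.0, 1.0
                else:
                    res = two_sample_t(a, b, variant=config.t_variant)
                    t_val, p_val = res.statistic, res.p_value
                nodal_rows.append({
                    "node_id": node, "metric": m, "t": t_val, "p": p_val,
                    "flag_strict": p_val < levels.strict,
                    "flag_liberal": p_val < levels.liberal,
                })
    nodal_df = pd.DataFrame(
        nodal_rows,
        columns=["node_id", "metric", "t", "p", "flag_strict",
                 "flag_liberal"])

    beh_rows = []
    if config.run_behavior:
        sig_metrics = global_df.loc[global_df["significant"], "metric"]
        pat_ids = [i for i, is_p in zip(ids, pat) if is_p]
        pat_clin = clin.loc[pat_ids]
        cov_cols = []
        for c in config.covariates:
            col = pat_clin[c]
            if col.dtype == object:
                col = (col == "M").astype(float)
            cov_cols.append(col.to_numpy(dtype=float))
        cov = np.column_stack(cov_cols) if cov_cols else np.empty(
            (len(pat_ids), 0))
        for m in sig_metrics:
            v = _auc_matrix(profiles, m, nodal=False)[pat]
            for score in CLINICAL_SCORES:
                if score not in pat_clin.columns:
                    continue
                y = pat_clin[score].to_numpy(dtype=float)
                if y.std() == 0 or v.std() == 0:
                    continue
                r_res = pearson_correlation(v, y)
                try:
                    pr_res = partial_correlation(v, y, cov)
                    pr, p_pr = pr_res.statistic, pr_res.p_value
                except ValueError:
                    pr, p_pr = np.nan, np.nan
                beh_rows.append({
                    "metric": m, "score": score,
                    "r": r_res.statistic, "p_r": r_res.p_value,
                    "partial_r": pr, "p_partial": p_pr,
                    "n": r_res.n,
                })
    behavior_df = pd.DataFrame(
        beh_rows, columns=["metric", "score", "r", "p_r", "partial_r",
                           "p_partial", "n"])
    return ComparisonTable(global_tests=global_df, nodal_tests=nodal_df,
                           behavior=behavior_df, alpha=config.alpha,
                           bonferroni=levels)
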