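"""Simulation studies validating the end-to-end pipeline.

Each experiment repeatedly generates synthetic cohorts, runs the
connectivity -> metrics -> statistics chain on them, and reports an
operating characteristic of the group test on the local-efficiency AUC
(the metric the lesion model perturbs most directly):

* :func:`type_one_error_rate` — rejection rate under the null
  (no lesion, no clinical coupling); should sit near the nominal alpha.
* :func:`lesion_detection_power` — rejection rate under the strong
  lesion model (within-module correlation 0.6 -> 0.25 in the lesioned
  modules).
* :func:`behavior_recovery_rate` — fraction of coupled cohorts in which
  the patient-group correlation between the Eloc AUC and the composite
  language score is positive and significant.

The default cohort dimensions (60 nodes in six equal modules, 150 time
points, 24 patients vs 19 controls) are the package's standard test-bed
conditions.
"""

from __future__ import annotations

import numpy as np

from .connectivity import ThresholdGrid, binarize_at_sparsity, \
    compute_fc_matrix
from .metrics import auc_over_grid, local_efficiency
from .stats import pearson_correlation, two_sample_t
from .synthetic import CohortConfig, coupled_config, generate_cohort, \
    null_config, strong_lesion_config

__all__ = [
    "eloc_auc_per_subject",
    "type_one_error_rate",
    "lesion_detection_power",
    "behavior_recovery_rate",
]


def eloc_auc_per_subject(series, grid: ThresholdGrid) -> np.ndarray:
    """Local-efficiency AUC for each subject's time series."""
    out = np.empty(len(series))
    for i, ts in enumerate(series):
        fc = compute_fc_matrix(ts)
        eloc = [local_efficiency(binarize_at_sparsity(fc, s))[0]
                for s in grid]
        out[i] = auc_over_grid(eloc, grid)
    return out


def _eloc_test_p(config: CohortConfig,
                 grid: ThresholdGrid) -> tuple[float, float, np.ndarray]:
    """(p-value, mean difference patient - control, patient AUCs)."""
    series, clinical = generate_cohort(config)
    auc = eloc_auc_per_subject(series, grid)
    pat = (clinical["group"] == "patient").to_numpy()
    res = two_sample_t(auc[pat], auc[~pat], variant="welch")
    diff = float(auc[pat].mean() - auc[~pat].mean())
    return res.p_value, diff, auc[pat]


def type_one_error_rate(n_cohorts: int = 500, seed: int = 0,
                        alpha: float = 0.05, **config_overrides) -> float:
    """Rejection rate of the Eloc-AUC Welch test across null cohorts."""
    grid = ThresholdGrid()
    seeds = _cohort_seeds(seed, n_cohorts)
    hits = 0
    for s in seeds:
        p, _, _ = _eloc_test_p(null_config(seed=int(s), **config_overrides),
                               grid)
        hits += p < alpha
    return hits / n_cohorts


def lesion_detection_power(n_cohorts: int = 20, seed: int = 0,
                           alpha: float = 0.05,
                           **config_overrides) -> float:
    """Rejection rate under the strong lesion model (power)."""
    grid = ThresholdGrid()
    seeds = _cohort_seeds(seed, n_cohorts)
    hits = 0
    for s in seeds:
        p, diff, _ = _eloc_test_p(
            strong_lesion_config(seed=int(s), **config_overrides), grid)
        hits += (p < alpha) and (diff < 0)
    return hits / n_cohorts


def behavior_recovery_rate(n_cohorts: int = 20, seed: int = 0,
                           alpha: float = 0.05,
                           **config_overrides) -> float:
    """Fraction of coupled cohorts with a significant positive
    Eloc-AUC vs. language-ability correlation in the patient group."""
    grid = ThresholdGrid()
    seeds = _cohort_seeds(seed, n_cohorts)
    hits = 0
    for s in seeds:
        config = coupled_config(seed=int(s), **config_overrides)
        series, clinical = generate_cohort(config)
        pat = (clinical["group"] == "patient").to_numpy()
        auc = eloc_auc_per_subject([t for t, p in zip(series, pat) if p],
                                   grid)
        lang = clinical.loc[pat, "language_ability"].to_numpy()
        res = pearson_correlation(auc, lang)
        hits += (res.statistic > 0) and (res.p_value < alpha)
    return hits / n_cohorts


def _cohort_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-cohort seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
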