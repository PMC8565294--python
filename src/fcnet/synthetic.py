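"""Synthetic resting-state cohorts with known ground truth.

Generates per-subject ROI time series and a clinical table that mimic the
structure of a two-group (post-stroke aphasia vs. healthy control)
resting-state fMRI study: modular inter-node covariance, a
patient-specific reduction of within-module connectivity in a designated
"lesioned" node subset, and language/cognition scores coupled to the
strength of that reduction.  Because the generating covariance and the
per-subject severity are known exactly, every downstream stage
(connectivity, graph metrics, group statistics) can be validated without
any real data.

Time points are drawn i.i.d. from a multivariate normal: graph
construction depends only on the inter-node correlation structure, so
temporal autocorrelation (removed upstream by band-pass filtering in a
real pipeline) is deliberately not modeled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ROITimeSeriesSet",
    "build_covariance",
    "generate_cohort",
    "write_cohort",
    "null_config",
    "strong_lesion_config",
    "coupled_config",
    "CLINICAL_COLUMNS",
]

#: column order of the clinical table
CLINICAL_COLUMNS = [
    "subject_id", "group", "age", "sex", "duration", "head_motion",
    "abc_spontaneous", "abc_auditory", "abc_repetition", "abc_naming",
    "language_ability", "mmse", "moca",
]

# Patient-group baselines for the four aphasia-battery sub-scores at
# maximal severity; with the default coupling (30) and full severity
# spread, coupling * (1 - severity) averages 15, landing the group
# means near typical published motor-aphasia cohort values
# (~53/76/74/54 for spontaneous speech / auditory comprehension /
# repetition / naming).
_ABC_BASELINES = {
    "abc_spontaneous": 38.0,
    "abc_auditory": 61.0,
    "abc_repetition": 59.0,
    "abc_naming": 39.0,
}


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Per-subject ROI signal table: T time points x N nodes."""

    subject_id: str
    data: np.ndarray
    node_ids: tuple[int, ...]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("time series must be a 2-D T x N array")
        t, n = data.shape
        if t < 2:
            raise ValueError(f"need at least 2 time points, got {t}")
        if n < 3:
            raise ValueError(f"need at least 3 nodes, got {n}")
        if len(self.node_ids) != n:
            raise ValueError("node_ids must match the number of columns")
        sd = data.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"subject {self.subject_id}: node {self.node_ids[bad]} has a "
                "constant signal"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-group cohort.

    ``rho_within``/``rho_between`` set the block-constant correlation
    structure; ``lesion_nodes`` marks the nodes whose modules lose
    within-module correlation in patients, scaled per subject by a latent
    severity in [0, 1] (drawn uniformly from
    ``[1 - subject_severity_spread, 1]``).  ``coupling`` (score units per
    unit of 1 - severity) ties the clinical scores to the same latent
    severity, making brain-behavior correlation recovery well-posed.
    """

    seed: int = 0
    n_patients: int = 24
    n_controls: int = 19
    n_nodes: int = 60
    n_timepoints: int = 150
    module_sizes: tuple[int, ...] = (10, 10, 10, 10, 10, 10)
    rho_within: float = 0.6
    rho_between: float = 0.1
    lesion_nodes: frozenset[int] = field(
        default_factory=lambda: frozenset(range(20)))
    lesion_strength: float = 0.7
    subject_severity_spread: float = 1.0
    clinical_noise_sd: float = 10.0
    coupling: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        object.__setattr__(self, "lesion_nodes", frozenset(self.lesion_nodes))
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups must be non-empty")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, "
                f"expected n_nodes={self.n_nodes}")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (0 <= self.rho_within < 1):
            raise ValueError("rho_within must be in [0, 1)")
        if not (0 <= self.rho_between < 1):
            raise ValueError("rho_between must be in [0, 1)")
        if self.rho_between > self.rho_within:
            raise ValueError("rho_between must not exceed rho_within")
        if not self.lesion_nodes <= set(range(self.n_nodes)):
            raise ValueError("lesion_nodes must be a subset of the node set")
        for name in ("lesion_strength", "subject_severity_spread"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clinical_noise_sd < 0:
            raise ValueError("clinical_noise_sd must be non-negative")

    @property
    def module_labels(self) -> np.ndarray:
        """Module index per node, following module_sizes order."""
        return np.repeat(np.arange(len(self.module_sizes)),
                         self.module_sizes)

    @property
    def lesioned_modules(self) -> frozenset[int]:
        labels = self.module_labels
        return frozenset(int(labels[i]) for i in self.lesion_nodes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["lesion_nodes"] = sorted(self.lesion_nodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["module_sizes"] = tuple(d["module_sizes"])
        d["lesion_nodes"] = frozenset(d["lesion_nodes"])
        return cls(**d)


def build_covariance(config: CohortConfig, severity: float) -> np.ndarray:
    """Node-by-node covariance (= correlation) matrix for one subject.

    Entries are ``rho_within`` inside a module and ``rho_between`` across
    modules; within every module touched by ``lesion_nodes`` the
    within-module entries are reduced to
    ``rho_within - severity * lesion_strength * (rho_within - rho_between)``.
    The diagonal is 1.  Raises if the result is not positive
    semi-definite (incompatible rho/lesion settings).
    """
    if not (0 <= severity <= 1):
        raise ValueError("severity must be in [0, 1]")
    n = config.n_nodes
    labels = config.module_labels
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, config.rho_within, config.rho_between)
    lesioned = config.lesioned_modules
    if lesioned and severity > 0 and config.lesion_strength > 0:
        rho_les = config.rho_within - severity * config.lesion_strength * (
            config.rho_within - config.rho_between)
        in_les = np.isin(labels, sorted(lesioned))
        mask = same & in_les[:, None] & in_les[None, :]
        cov = np.where(mask, rho_les, cov)
    np.fill_diagonal(cov, 1.0)
    w = np.linalg.eigvalsh(cov)
    if w[0] < -1e-10:
        raise ValueError(
            "covariance is not positive semi-definite "
            f"(min eigenvalue {w[0]:.3e}); rho/lesion settings incompatible")
    return cov


def _sample_series(rng: np.random.Generator, cov: np.ndarray,
                   t: int) -> np.ndarray:
    # eigh-based square root: PSD-safe even when clipping tiny negatives
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((t, cov.shape[0])) @ root.T


def _truncate(x, lo, hi):
    return np.clip(x, lo, hi)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ROITimeSeriesSet], pd.DataFrame]:
    """Draw one full cohort: time series per subject plus clinical table.

    Patients receive a latent severity ~ U[1 - spread, 1]; controls have
    severity 0.  Each aphasia-battery sub-score is
    ``baseline + coupling * (1 - severity) + N(0, clinical_noise_sd)``
    truncated to [0, 100]; controls sit near ceiling.  The composite
    language ability is the arithmetic mean of the four sub-scores.
    A fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_pat, n_con = config.n_patients, config.n_controls
    lo = 1.0 - config.subject_severity_spread
    severities = np.concatenate([
        rng.uniform(lo, 1.0, size=n_pat),
        np.zeros(n_con),
    ])
    groups = ["patient"] * n_pat + ["control"] * n_con
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_pat + n_con)]

    cov_control = build_covariance(config, 0.0)
    series: list[ROITimeSeriesSet] = []
    node_ids = tuple(range(config.n_nodes))
    for sid, grp, sev in zip(subject_ids, groups, severities):
        cov = cov_control if grp == "control" else build_covariance(
            config, float(sev))
        data = _sample_series(rng, cov, config.n_timepoints)
        series.append(ROITimeSeriesSet(sid, data, node_ids))

    rows = []
    for sid, grp, sev in zip(subject_ids, groups, severities):
        is_pat = grp == "patient"
        age = float(_truncate(
            rng.normal(48.4 if is_pat else 53.7, 10.7 if is_pat else 9.3),
            18, 70))
        sex = "M" if rng.random() < (2 / 3 if is_pat else 0.53) else "F"
        duration = float(_truncate(rng.exponential(5.2), 1, 24)) if is_pat \
            else 0.0
        head_motion = float(abs(rng.normal(0.10, 0.04)))
        abc = {}
        for name, base in _ABC_BASELINES.items():
            if is_pat:
                score = (base + config.coupling * (1.0 - sev)
                         + rng.normal(0.0, config.clinical_noise_sd))
            else:
                score = 100.0 - abs(rng.normal(0.0, 0.6))
            abc[name] = float(_truncate(score, 0, 100))
        language = float(np.mean(list(abc.values())))
        if is_pat:
            mmse = 7.0 + 15.0 * (1.0 - sev) + rng.normal(0.0, 3.0)
            moca = 5.0 + 15.0 * (1.0 - sev) + rng.normal(0.0, 3.0)
        else:
            mmse = rng.normal(29.2, 0.9)
            moca = rng.normal(28.6, 0.9)
        rows.append({
            "subject_id": sid, "group": grp, "age": age, "sex": sex,
            "duration": duration, "head_motion": head_motion, **abc,
            "language_ability": language,
            "mmse": float(_truncate(mmse, 0, 30)),
            "moca": float(_truncate(moca, 0, 30)),
            "severity": float(sev),
        })
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS + ["severity"])
    return series, clinical


def write_cohort(directory, series: list[ROITimeSeriesSet],
                 clinical: pd.DataFrame, config: CohortConfig) -> None:
    """Write one TSV per subject, clinical.csv, nodes.csv and a JSON
    sidecar recording the full config (including the seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ts in series:
        np.savetxt(directory / f"{ts.subject_id}_timeseries.tsv", ts.data,
                   delimiter="\t", fmt="%.6f")
    clinical.to_csv(directory / "clinical.csv", index=False)
    labels = config.module_labels
    rng = np.random.default_rng(config.seed + 1)
    coords = rng.uniform(-70, 70, size=(config.n_nodes, 3)).round(1)
    nodes = pd.DataFrame({
        "node_id": np.arange(config.n_nodes),
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "label": [f"node_{i:03d}" for i in range(config.n_nodes)],
        "module": labels,
    })
    nodes.to_csv(directory / "nodes.csv", index=False)
    with open(directory / "cohort_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Ready-made study conditions

def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """No group difference: lesion_strength 0, scores uncoupled."""
    kw = dict(seed=seed, lesion_strength=0.0, coupling=0.0)
    kw.update(overrides)
    return CohortConfig(**kw)


def strong_lesion_config(seed: int = 0, **overrides) -> CohortConfig:
    """Every patient's lesioned-module correlation drops 0.6 -> 0.25
    (severity fixed at 1, strength 0.7 on the 0.6/0.1 block structure)."""
    kw = dict(seed=seed, rho_within=0.6, rho_between=0.1,
              lesion_strength=0.7, subject_severity_spread=0.0)
    kw.update(overrides)
    return CohortConfig(**kw)


def coupled_config(seed: int = 0, **overrides) -> CohortConfig:
    """Graded lesion severity coupled to the clinical scores
    (coupling 30 score units, noise sd 10)."""
    kw = dict(seed=seed, rho_within=0.6, rho_between=0.1,
              lesion_strength=0.7, subject_severity_spread=1.0,
              coupling=30.0, clinical_noise_sd=10.0)
    kw.update(overrides)
    return CohortConfig(**kw)
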