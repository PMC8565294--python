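"""End-to-end orchestration: simulate -> connectivity -> metrics -> stats.

A run is driven by a :class:`RunConfig` (loadable from YAML or JSON) and
writes each stage's outputs to its own subdirectory of the output
directory.  Completed stages are marked with a ``_done.json`` file
recording a hash of the configuration, so re-running the same config
resumes instead of recomputing; the final ``report.json`` carries
per-file checksums, every seed used, package versions and collected
warnings, and is byte-identical across re-runs of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import ThresholdGrid, binarize_at_sparsity, \
    compute_fc_matrix, load_cohort_dir, write_fc_tsv, write_edge_list
from .metrics import profile_subject
from .stats import StatsConfig, compare_groups
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("fcnet")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    Either ``cohort`` (simulate a synthetic cohort) or ``input_dir``
    (read an existing cohort of subject TSVs + clinical.csv) must be
    set.  The threshold grid is given as (start, stop, step) with the
    conventional defaults 0.05-0.40 in steps of 0.05; step 0.01 is the
    usual robustness alternative.
    """

    out_dir: str = "fcnet_out"
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    grid_start: float = 0.05
    grid_stop: float = 0.40
    grid_step: float = 0.05
    n_nulls: int = 0
    null_seed: int = 0
    stats: StatsConfig = field(default_factory=StatsConfig)
    write_edge_lists: bool = False

    def __post_init__(self):
        if self.cohort is None and self.input_dir is None:
            raise ValueError("either cohort or input_dir must be given")
        n = (self.grid_stop - self.grid_start) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid step must divide (stop - start)")

    @property
    def grid(self) -> ThresholdGrid:
        return ThresholdGrid.from_range(self.grid_start, self.grid_stop,
                                        self.grid_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        d["stats"] = dataclasses.asdict(self.stats)
        d["stats"]["covariates"] = list(self.stats.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if d.get("stats") is not None:
            s = dict(d["stats"])
            s["covariates"] = tuple(s.get("covariates", ()))
            d["stats"] = StatsConfig(**s)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # the computation, not its location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / "_done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, cfg_hash: str) -> None:
    (stage_dir / "_done.json").write_text(
        json.dumps({"config_hash": cfg_hash}))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``report.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    collected_warnings: list[str] = []
    grid = cfg.grid

    # --- stage 1: cohort ---------------------------------------------------
    if cfg.cohort is not None:
        stage = out / "cohort"
        if not _stage_done(stage, cfg_hash):
            log.info("stage simulate: %d subjects",
                     cfg.cohort.n_patients + cfg.cohort.n_controls)
            series, clinical = generate_cohort(cfg.cohort)
            write_cohort(stage, series, clinical, cfg.cohort)
            _mark_done(stage, cfg_hash)
        cohort_dir = stage
    else:
        cohort_dir = Path(cfg.input_dir)
    try:
        series, clinical = load_cohort_dir(cohort_dir)
    except FileNotFoundError as exc:
        raise RuntimeError(f"stage connectivity aborted: {exc}") from exc

    # --- stage 2: connectivity --------------------------------------------
    fc_dir = out / "fc"
    if not _stage_done(fc_dir, cfg_hash):
        fc_dir.mkdir(exist_ok=True)
        for ts in series:
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    fc = compute_fc_matrix(ts)
                    write_fc_tsv(fc, fc_dir / f"{ts.subject_id}_fc.tsv")
                    if cfg.write_edge_lists:
                        for s in grid:
                            g = binarize_at_sparsity(fc, s)
                            write_edge_list(
                                g, fc_dir
                                / f"{ts.subject_id}_s{s:.2f}_edges.tsv")
                collected_warnings += [
                    f"{ts.subject_id}: {w.message}" for w in wlist]
            except ValueError as exc:
                raise RuntimeError(
                    f"stage connectivity failed on {ts.subject_id}: {exc}"
                ) from exc
        _mark_done(fc_dir, cfg_hash)

    # --- stage 3: metrics --------------------------------------------------
    met_dir = out / "metrics"
    profiles = []
    met_dir.mkdir(exist_ok=True)
    recompute = not _stage_done(met_dir, cfg_hash)
    for idx, ts in enumerate(series):
        log.info("stage metrics: %s (%d/%d)", ts.subject_id, idx + 1,
                 len(series))
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                fc = compute_fc_matrix(ts)
                prof = profile_subject(fc, grid, n_nulls=cfg.n_nulls,
                                       seed=cfg.null_seed + idx)
            collected_warnings += [
                f"{ts.subject_id}: {w.message}" for w in wlist]
            for s in prof.disconnected_at:
                collected_warnings.append(
                    f"{ts.subject_id}: disconnected at sparsity {s}")
        except ValueError as exc:
            raise RuntimeError(
                f"stage metrics failed on {ts.subject_id}: {exc}") from exc
        profiles.append(prof)
        if recompute:
            sub_dir = met_dir / ts.subject_id
            sub_dir.mkdir(exist_ok=True)
            prof.global_metrics.to_csv(sub_dir / "global_metrics.tsv",
                                       sep="\t", float_format="%.8f")
            prof.nodal_metrics.to_csv(sub_dir / "nodal_metrics.tsv",
                                      sep="\t", index=False,
                                      float_format="%.8f")
            auc = prof.auc_nodal.copy()
            auc.to_csv(sub_dir / "auc_nodal.tsv", sep="\t",
                       float_format="%.8f")
            prof.auc_global.to_csv(sub_dir / "auc_global.tsv", sep="\t",
                                   float_format="%.8f", header=False)
    if recompute:
        _mark_done(met_dir, cfg_hash)

    # --- stage 4: statistics -----------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    try:
        table = compare_groups(profiles, clinical, cfg.stats)
    except ValueError as exc:
        raise RuntimeError(f"stage stats failed: {exc}") from exc
    table.global_tests.to_csv(stats_dir / "group_global.tsv", sep="\t",
                              index=False, float_format="%.8g")
    table.nodal_tests.to_csv(stats_dir / "group_nodal.tsv", sep="\t",
                             index=False, float_format="%.8g")
    table.behavior.to_csv(stats_dir / "brain_behavior.tsv", sep="\t",
                          index=False, float_format="%.8g")
    summary = {
        "alpha": table.alpha,
        "bonferroni_strict": table.bonferroni.strict,
        "bonferroni_liberal": table.bonferroni.liberal,
        "significant_global": table.global_tests.loc[
            table.global_tests["significant"], "metric"].tolist(),
        "n_nodal_flag_strict": int(
            table.nodal_tests["flag_strict"].sum())
        if len(table.nodal_tests) else 0,
    }
    (stats_dir / "summary.json").write_text(json.dumps(summary, indent=2))

    # --- report ------------------------------------------------------------
    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("report.json",):
            checksums[str(path.relative_to(out))] = _sha256(path)
    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg_hash,
        "version": __version__,
        "n_subjects": len(series),
        "grid": list(grid.sparsities),
        "warnings": collected_warnings,
        "summary": summary,
        "checksums": checksums,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report


def validate_inputs(directory) -> list[dict]:
    """Check a cohort directory without mutating it.

    Verifies per-subject T x N shape consistency, absence of constant
    columns, clinical/subject ID agreement, and node-table integrity.
    Returns a machine-readable list of issues (empty when clean).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    issues: list[dict] = []
    ts_paths = sorted(directory.glob("*_timeseries.tsv"))
    shapes = {}
    ts_ids = set()
    for path in ts_paths:
        sid = path.stem.replace("_timeseries", "")
        ts_ids.add(sid)
        try:
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            issues.append({"kind": "unreadable", "subject": sid,
                           "detail": str(exc)})
            continue
        shapes[sid] = data.shape
        sd = data.std(axis=0)
        for node in np.flatnonzero(sd == 0):
            issues.append({"kind": "constant_column", "subject": sid,
                           "node": int(node)})
    if len(set(shapes.values())) > 1:
        issues.append({"kind": "shape_mismatch",
                       "detail": {k: list(v) for k, v in shapes.items()}})
    clin_path = directory / "clinical.csv"
    if not clin_path.exists():
        issues.append({"kind": "missing_file", "detail": "clinical.csv"})
    else:
        clinical = pd.read_csv(clin_path)
        clin_ids = set(clinical["subject_id"])
        for sid in sorted(clin_ids - ts_ids):
            issues.append({"kind": "orphan_clinical_row", "subject": sid})
        for sid in sorted(ts_ids - clin_ids):
            issues.append({"kind": "missing_clinical_row", "subject": sid})
        if "group" in clinical.columns:
            bad = set(clinical["group"]) - {"patient", "control"}
            if bad:
                issues.append({"kind": "unknown_group",
                               "detail": sorted(bad)})
    nodes_path = directory / "nodes.csv"
    if nodes_path.exists() and shapes:
        nodes = pd.read_csv(nodes_path)
        n_nodes = next(iter(shapes.values()))[1]
        if len(nodes) != n_nodes:
            issues.append({"kind": "node_table_size",
                           "detail": f"{len(nodes)} rows vs {n_nodes} "
                                     "time-series columns"})
        if nodes["node_id"].duplicated().any():
            issues.append({"kind": "duplicate_node_id"})
    return issues
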