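"""Two-phase benchmarking pipeline.

Phase I runs the four ordinary clusterers (K-means, hierarchical, DBSCAN,
EM) at a common k and scores them by mean silhouette and RPT.  Phase II runs
ordinary K-means against the three hybrid initializations and reports the
full validity-index row plus the iteration count of each run.  ``run_study``
drives both phases over a configured set of datasets and writes JSON and
TSV reports that are byte-reproducible from the config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .baselines import agglomerative, dbscan, em_gmm
from .datasets import Dataset, load_table, standardize
from .exceptions import ConfigError
from .initializers import GAConfig, ga_init, hier_init, mst_init, tree_cut_labels
from .kmeans import best_of_restarts, run_kmeans
from .synthetic import emulate_profile
from .validity import (REPORT_COLUMNS, evaluate_partition, rpt, select_k,
                       silhouette_mean)

logger = logging.getLogger(__name__)

PHASE1_METHODS = ("K_Means", "Hierarchical", "DBScan", "EM")
PHASE2_METHODS = ("K_Means", "K+H", "K+MST", "K+GA")

#: cheaper GA settings used only inside RPT bootstrap refits
GA_BOOTSTRAP = dict(pop_size=20, generations=30)


class Phase1Entry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    silhouette: Optional[float]
    rpt: Optional[float]
    params: dict[str, Any]


class Phase2Row(BaseModel):
    model_config = ConfigDict(extra="forbid")
    I: int
    SSE: float
    Si: float
    RPT: float
    Dunn: float
    RI: Optional[float] = None
    ARI: Optional[float] = None
    AC: Optional[float] = None
    F: Optional[float] = None
    HI: Optional[float] = None
    VI: Optional[float] = None


class Provenance(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    restarts: int
    rpt_B: int
    gap_B: int
    ga: dict[str, Any]
    config_hash: str
    version: str


class StudyReport(BaseModel):
    """One dataset's results in the shape of the published tables."""

    model_config = ConfigDict(extra="forbid")
    dataset: str
    k_used: int
    k_votes: Optional[dict[str, int]] = None
    phase1: dict[str, Phase1Entry]
    phase1_best: dict[str, str]
    phase2: dict[str, Phase2Row]
    convergence: dict[str, int]
    provenance: Provenance


def _phase1_partitions(X: np.ndarray, k: int, restarts: int, seed: int,
                       min_pts: int, linkage: str):
    km = best_of_restarts(X, k, restarts=restarts, seed=seed)
    hi = agglomerative(X, k, linkage=linkage)
    db = dbscan(X, eps="auto", min_pts=min_pts)
    em = em_gmm(X, k, restarts=5, seed=seed)
    return {
        "K_Means": (km, {"restarts": restarts, "seed": seed},
                    lambda Xb, K, s: best_of_restarts(Xb, K, 5, s).labels),
        "Hierarchical": (hi.partition, hi.params,
                         lambda Xb, K, s: tree_cut_labels(Xb, K, linkage)),
        "DBScan": (db.partition, db.params,
                   lambda Xb, K, s, e=db.params["eps"]: dbscan(Xb, e, min_pts).partition.labels),
        "EM": (em.partition, em.params,
               lambda Xb, K, s: em_gmm(Xb, K, restarts=2, seed=s).partition.labels),
    }


def run_phase1(ds: Dataset, k: int, seed: int = 0, restarts: int = 25,
               rpt_B: int = 30, min_pts: int = 4,
               linkage: str = "ward") -> tuple[dict[str, Phase1Entry], dict[str, str]]:
    """Silhouette/RPT comparison of the four ordinary clusterers at a common k."""
    X = ds.X
    out: dict[str, Phase1Entry] = {}
    for name, (part, params, refit) in _phase1_partitions(
            X, k, restarts, seed, min_pts, linkage).items():
        keep = part.labels >= 0
        n_clusters = int(np.unique(part.labels[keep]).size) if keep.any() else 0
        if n_clusters < 2:
            logger.warning("phase1 %s produced %d cluster(s); silhouette undefined",
                           name, n_clusters)
            si_val, rpt_val = None, None
        else:
            si_val = silhouette_mean(X[keep], part.labels[keep])
            rpt_val = rpt(X, part.labels, B=rpt_B, seed=seed, recluster=refit)
        out[name] = Phase1Entry(silhouette=si_val, rpt=rpt_val,
                                params=dict(params, noise_points=int((~keep).sum())))
    best = {}
    for index in ("silhouette", "rpt"):
        scored = {m: getattr(e, index) for m, e in out.items() if getattr(e, index) is not None}
        if scored:
            best[index] = max(scored, key=lambda m: scored[m])
    return out, best


def phase2_partitions(X: np.ndarray, k: int, ga_cfg: GAConfig,
                      restarts: int = 25, seed: int = 0, linkage: str = "ward"):
    """The four Phase-II runs, in report order."""
    return {
        "K_Means": best_of_restarts(X, k, restarts=restarts, seed=seed),
        "K+H": run_kmeans(X, hier_init(X, k, linkage)),
        "K+MST": run_kmeans(X, mst_init(X, k)),
        "K+GA": run_kmeans(X, ga_init(X, k, ga_cfg)),
    }


def run_phase2(ds: Dataset, k: int, ga_cfg: Optional[GAConfig] = None,
               restarts: int = 25, seed: int = 0, rpt_B: int = 30,
               linkage: str = "ward") -> tuple[dict[str, Phase2Row], dict[str, int]]:
    """Ordinary vs hybrid K-means: full validity row and iterations per method."""
    ga_cfg = ga_cfg or GAConfig(seed=seed)
    X = ds.X
    parts = phase2_partitions(X, k, ga_cfg, restarts=restarts, seed=seed, linkage=linkage)
    boot_ga = GAConfig(seed=seed, crossover_rate=ga_cfg.crossover_rate,
                       mutation_rate=ga_cfg.mutation_rate, elitism=ga_cfg.elitism,
                       **GA_BOOTSTRAP)
    refits = {
        "K_Means": lambda Xb, K, s: best_of_restarts(Xb, K, 5, s).labels,
        "K+H": lambda Xb, K, s: run_kmeans(Xb, hier_init(Xb, K, linkage)).labels,
        "K+MST": lambda Xb, K, s: run_kmeans(Xb, mst_init(Xb, K)).labels,
        "K+GA": lambda Xb, K, s: run_kmeans(
            Xb, ga_init(Xb, K, GAConfig(seed=s, **GA_BOOTSTRAP))).labels,
    }
    rows: dict[str, Phase2Row] = {}
    convergence: dict[str, int] = {}
    for name in PHASE2_METHODS:
        part = parts[name]
        rep = evaluate_partition(X, part, truth=ds.labels, rpt_B=rpt_B,
                                 seed=seed, recluster=refits[name])
        rows[name] = Phase2Row(**{key: val for key, val in rep.as_row().items()})
        convergence[name] = part.iterations
    return rows, convergence


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

def _load_configured_dataset(entry: dict[str, Any], seed: int) -> Dataset:
    source = entry.get("source", "synthetic")
    name = entry.get("name")
    if source == "csv":
        ds = load_table(entry["path"], label_column=entry.get("label_column"),
                        name=name)
    elif source == "synthetic":
        ds = emulate_profile(name, separation=float(entry.get("separation", 3.0)),
                             seed=int(entry.get("seed", seed)))
    elif source == "bundled":
        from sklearn.datasets import load_iris, load_wine
        loaders = {"iris": load_iris, "wine": load_wine}
        if name not in loaders:
            raise ConfigError(f"bundled source supports {sorted(loaders)}, got {name!r}")
        bunch = loaders[name]()
        ds = Dataset(name=name, X=bunch.data.astype(float),
                     labels=bunch.target.astype(int),
                     feature_names=list(bunch.feature_names))
    else:
        raise ConfigError(f"unknown dataset source {source!r}")
    return standardize(ds)


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_study(config: dict[str, Any],
              out_dir: str | Path | None = None) -> list[StudyReport]:
    """Run both phases for every configured dataset and write JSON/TSV reports."""
    seed = int(config.get("seed", 0))
    restarts = int(config.get("restarts", 25))
    rpt_B = int(config.get("rpt_B", 30))
    gap_B = int(config.get("gap_B", 20))
    ga_opts = dict(config.get("ga", {}))
    ga_cfg = GAConfig(seed=int(ga_opts.pop("seed", seed)), **ga_opts)
    linkage = config.get("linkage", "ward")
    k_setting = config.get("k", "auto")
    chash = _config_hash(config)

    out_path = Path(out_dir or config.get("out_dir", "reports"))
    out_path.mkdir(parents=True, exist_ok=True)

    reports: list[StudyReport] = []
    for entry in config.get("datasets", []):
        ds = _load_configured_dataset(entry, seed)
        logger.info("study: dataset %s (n=%d, d=%d)", ds.name, ds.n, ds.d)
        k_votes = None
        k_override = entry.get("k", k_setting)
        if k_override == "auto":
            sel = select_k(ds.X, k_range=(2, 15), gap_B=gap_B, seed=seed)
            k_used = sel.k_final
            k_votes = {"elbow": sel.k_elbow, "gap": sel.k_gap,
                       "silhouette": sel.k_silhouette, "final": sel.k_final}
        else:
            k_used = int(k_override)

        phase1, best = run_phase1(ds, k_used, seed=seed, restarts=restarts,
                                  rpt_B=rpt_B, linkage=linkage)
        phase2, convergence = run_phase2(ds, k_used, ga_cfg=ga_cfg,
                                         restarts=restarts, seed=seed,
                                         rpt_B=rpt_B, linkage=linkage)
        report = StudyReport(
            dataset=ds.name, k_used=k_used, k_votes=k_votes,
            phase1=phase1, phase1_best=best, phase2=phase2,
            convergence=convergence,
            provenance=Provenance(seed=seed, restarts=restarts, rpt_B=rpt_B,
                                  gap_B=gap_B, ga=ga_cfg.__dict__,
                                  config_hash=chash, version=__version__),
        )
        reports.append(report)
        stem = out_path / ds.name
        stem.with_suffix(".json").write_text(
            json.dumps(report.model_dump(), indent=2) + "\n")
        stem.with_suffix(".tsv").write_text(report_tsv(report))
    return reports


def report_tsv(report: StudyReport) -> str:
    """Phase-II rows as TSV in the published column order."""
    lines = ["Method\t" + "\t".join(REPORT_COLUMNS)]
    for method in PHASE2_METHODS:
        row = report.phase2[method]
        cells = [method]
        for col in REPORT_COLUMNS:
            val = getattr(row, col)
            cells.append("" if val is None else f"{val:.6g}")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def validate_report(payload: dict[str, Any]) -> StudyReport:
    """Validate a serialized report against the shipped schema (pydantic model)."""
    return StudyReport.model_validate(payload)
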