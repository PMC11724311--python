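"""The five-step droplet filtering pipeline.

Steps: (1) initial filter on detected genes and mitochondrial percentage;
(2) min-max scaling of the clustering features over surviving droplets;
(3) k-means partitioning (default k=4) and removal of the cluster(s) with
the lowest mean unspliced fraction, predicted to hold empty droplets;
(4) outlier filtering anchored on a reference cluster — the unspliced
fraction must fall below Q1(reference) minus an offset AND the
mitochondrial percentage must exceed Q3(reference) plus an offset for a
droplet to be removed; (5) doublet removal via simulated-doublet scoring.

Retained sets are nested across steps and every droplet carries exactly
one final status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.preprocessing import MinMaxScaler

from . import __version__
from .doublets import score_doublets
from .genesets import GeneSetRegistry, resolve
from .io import DropletMatrix
from .metrics import BRAIN_FEATURES, HEART_FEATURES, build_feature_table

STATUSES = (
    "retained",
    "no_splicing_info",
    "init_genes_low",
    "init_genes_high",
    "init_mito_high",
    "cluster_removed",
    "outlier_removed",
    "doublet_removed",
)

STEP_NAMES = ("splicing_info", "initial_filter", "cluster_removal", "outlier_filter", "doublet_filter")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Tunables for a pipeline run; defaults are the heart settings."""

    min_genes: int = 500
    max_genes: int = 6000
    max_pct_mito_initial: float = 40.0
    k: int = 4
    clusters_to_remove: int = 1
    removal_criterion: str = "lowest_mean_unspliced"
    reference_cluster_rule: str = "highest_mean_nonCM"
    unspliced_offset: float = 0.1
    mito_offset: float = 5.0
    doublet_threshold: float = 0.1
    feature_list: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.clusters_to_remove < self.k):
            raise PipelineError(
                f"clusters_to_remove must satisfy 1 <= value < k "
                f"(got {self.clusters_to_remove}, k={self.k})"
            )
        if self.min_genes >= self.max_genes:
            raise PipelineError("min_genes must be below max_genes")
        if self.unspliced_offset < 0 or self.mito_offset < 0:
            raise PipelineError("offsets must be non-negative")
        if self.removal_criterion != "lowest_mean_unspliced":
            raise PipelineError(f"unknown removal_criterion {self.removal_criterion!r}")
        if self.reference_cluster_rule not in ("highest_mean_nonCM", "highest_mean_unspliced"):
            raise PipelineError(
                f"unknown reference_cluster_rule {self.reference_cluster_rule!r}"
            )

    @classmethod
    def for_tissue(cls, tissue: str, **overrides) -> "PipelineConfig":
        """Default config for ``heart`` or ``brain``.

        Brain drops the cardiomyocyte features, lowers the detected-genes
        floor to 400, clusters into three groups and anchors the outlier
        filter on the highest-mean-unspliced cluster.
        """
        if tissue == "heart":
            base: dict = {"feature_list": list(HEART_FEATURES)}
        elif tissue == "brain":
            base = {
                "min_genes": 400,
                "k": 3,
                "reference_cluster_rule": "highest_mean_unspliced",
                "feature_list": list(BRAIN_FEATURES),
            }
        else:
            raise PipelineError(f"no default config for tissue {tissue!r}")
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class FilterResult:
    """Per-droplet outcome of a pipeline run.

    ``report`` has one row per input droplet, input order: barcode, metric
    values, cluster label (droplets reaching step 3), per-step retained
    flags and final status. ``masks`` maps step name to the boolean
    retained-after-step vector; the sets are nested. ``applied_thresholds``
    records the outlier thresholds and reference cluster actually used.
    """

    report: pd.DataFrame
    masks: dict[str, np.ndarray]
    applied_thresholds: dict
    config: PipelineConfig
    seed: int

    @property
    def status(self) -> pd.Series:
        return self.report["status"]

    @property
    def retained_barcodes(self) -> list[str]:
        return self.report.loc[self.report["status"] == "retained", "barcode"].tolist()

    def counts_by_status(self) -> dict[str, int]:
        return {s: int((self.report["status"] == s).sum()) for s in STATUSES}

    def manifest(self) -> dict:
        return {
            "package": "qclus",
            "version": __version__,
            "seed": int(self.seed),
            "config": _jsonable(self.config.to_dict()),
            "applied_thresholds": _jsonable(self.applied_thresholds),
            "n_droplets": int(len(self.report)),
            "status_counts": self.counts_by_status(),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def initial_filter(table: pd.DataFrame, cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Detected-genes and mitochondrial bounds; bounds are inclusive.

    Returns ``(mask, reasons)``: retained iff
    ``min_genes <= n_genes <= max_genes`` and
    ``pct_mito <= max_pct_mito_initial``. ``reasons`` names the first
    violated bound for removed droplets ('' for retained ones).
    """
    n_genes = table["n_genes"].to_numpy()
    pct_mito = table["pct_mito"].to_numpy()
    reasons = np.full(len(table), "", dtype=object)
    reasons[n_genes < cfg.min_genes] = "init_genes_low"
    high = (reasons == "") & (n_genes > cfg.max_genes)
    reasons[high] = "init_genes_high"
    mito = (reasons == "") & (pct_mito > cfg.max_pct_mito_initial)
    reasons[mito] = "init_mito_high"
    return reasons == "", reasons


def scale_features(table: pd.DataFrame, feature_list: Sequence[str]) -> np.ndarray:
    """Min-max scale each clustering feature to [0, 1] over the given rows.

    A constant feature maps to all zeros.
    """
    missing = [f for f in feature_list if f not in table.columns]
    if missing:
        raise PipelineError(f"feature(s) not in table: {missing}")
    values = table.loc[:, list(feature_list)].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise PipelineError("clustering features contain NaN")
    return MinMaxScaler().fit_transform(values)


def cluster_droplets(scaled: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """k-means labels on the scaled feature matrix; deterministic per seed."""
    if scaled.shape[0] < cfg.k:
        raise PipelineError(
            f"too few droplets to cluster ({scaled.shape[0]} < k={cfg.k})"
        )
    km = KMeans(n_clusters=cfg.k, n_init=10, random_state=cfg.seed, max_iter=300, tol=1e-4)
    return km.fit_predict(scaled)


def select_removal_clusters(
    labels: np.ndarray, table: pd.DataFrame, cfg: PipelineConfig
) -> set[int]:
    """The ``clusters_to_remove`` clusters with the lowest mean unspliced fraction.

    These are predicted to hold empty droplets. Ties break toward the lower
    cluster index.
    """
    if cfg.clusters_to_remove >= cfg.k:
        raise PipelineError("clusters_to_remove must be below k")
    frac = table["fraction_unspliced"].to_numpy()
    cluster_ids = np.unique(labels)
    means = np.array([frac[labels == c].mean() for c in cluster_ids])
    order = np.lexsort((cluster_ids, means))  # mean ascending, index as tie-break
    return {int(cluster_ids[i]) for i in order[: cfg.clusters_to_remove]}


def _reference_cluster(
    labels: np.ndarray, table: pd.DataFrame, removed: set[int], cfg: PipelineConfig
) -> int:
    metric = {
        "highest_mean_nonCM": "pct_nonCM_max",
        "highest_mean_unspliced": "fraction_unspliced",
    }[cfg.reference_cluster_rule]
    vals = table[metric].to_numpy()
    candidates = [c for c in np.unique(labels) if c not in removed]
    if not candidates:
        raise PipelineError("no non-removed cluster to use as reference")
    means = np.array([vals[labels == c].mean() for c in candidates])
    # highest mean; ties toward the lower cluster index
    order = np.lexsort((candidates, -means))
    return int(candidates[order[0]])


def outlier_filter(
    table: pd.DataFrame,
    labels: np.ndarray,
    removed_clusters: set[int],
    cfg: PipelineConfig,
) -> tuple[np.ndarray, dict]:
    """Joint unspliced/mitochondrial outlier removal anchored on a reference cluster.

    Thresholds: ``T_u = Q1(fraction_unspliced in reference) -
    unspliced_offset`` and ``T_m = Q3(pct_mito in reference) + mito_offset``
    (quartiles by linear interpolation). A droplet is removed only when it
    violates both: ``fraction_unspliced < T_u`` and ``pct_mito > T_m``.
    Returns the retained mask over the given rows plus the applied
    thresholds.
    """
    ref = _reference_cluster(labels, table, removed_clusters, cfg)
    in_ref = labels == ref
    if not in_ref.any():
        raise PipelineError("reference cluster is empty")
    t_u = float(np.percentile(table.loc[in_ref, "fraction_unspliced"], 25)) - cfg.unspliced_offset
    t_m = float(np.percentile(table.loc[in_ref, "pct_mito"], 75)) + cfg.mito_offset
    frac = table["fraction_unspliced"].to_numpy()
    mito = table["pct_mito"].to_numpy()
    removed = (frac < t_u) & (mito > t_m)
    thresholds = {
        "unspliced_threshold": t_u,
        "mito_threshold": t_m,
        "reference_cluster": ref,
    }
    return ~removed, thresholds


def doublet_filter(scores: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Retained mask: a droplet is removed iff its score strictly exceeds the threshold."""
    return ~(np.asarray(scores) > cfg.doublet_threshold)


def run_qclus(
    matrix: DropletMatrix,
    registry: GeneSetRegistry,
    cfg: PipelineConfig | None = None,
    feature_table: pd.DataFrame | None = None,
    doublet_scorer: Callable[[sp.spmatrix, int], np.ndarray] | None = None,
) -> FilterResult:
    """Run the full pipeline and return a :class:`FilterResult`.

    ``feature_table`` may be supplied to skip metric computation (it must
    follow the matrix barcode order). ``doublet_scorer`` substitutes the
    built-in simulated-doublet scorer; it receives the count matrix
    restricted to surviving droplets plus the seed.
    """
    if cfg is None:
        cfg = PipelineConfig.for_tissue(registry.tissue if registry.tissue in ("heart", "brain") else "heart")
    resolved = resolve(registry, matrix.genes)
    if feature_table is None:
        feature_table = build_feature_table(matrix, registry, resolved)
    if len(feature_table) != matrix.n_droplets:
        raise PipelineError("feature table row count does not match the matrix")
    features = cfg.feature_list
    if features is None:
        features = list(HEART_FEATURES) if registry.by_role("cm_cytoplasmic") else list(BRAIN_FEATURES)

    n = matrix.n_droplets
    status = np.full(n, "retained", dtype=object)
    masks: dict[str, np.ndarray] = {}

    # Step 0: droplets with no usable unspliced fraction cannot be clustered
    no_splice = feature_table["fraction_unspliced"].isna().to_numpy()
    status[no_splice] = "no_splicing_info"
    masks["splicing_info"] = ~no_splice

    # Step 1: initial bounds
    keep1, reasons = initial_filter(feature_table, cfg)
    step1 = masks["splicing_info"] & keep1
    newly = masks["splicing_info"] & ~keep1
    status[newly] = reasons[newly]
    masks["initial_filter"] = step1

    alive = np.flatnonzero(step1)
    if len(alive) < cfg.k:
        raise PipelineError(
            f"too few droplets to cluster ({len(alive)} survive the initial filter, k={cfg.k})"
        )
    sub = feature_table.iloc[alive]

    # Steps 2-3: scale, cluster, drop the lowest-unspliced cluster(s)
    scaled = scale_features(sub, features)
    labels = cluster_droplets(scaled, cfg)
    removed_clusters = select_removal_clusters(labels, sub, cfg)
    cluster_col = np.full(n, -1, dtype=int)
    cluster_col[alive] = labels
    in_removed = np.isin(labels, list(removed_clusters))
    status[alive[in_removed]] = "cluster_removed"
    step3 = masks["initial_filter"].copy()
    step3[alive[in_removed]] = False
    masks["cluster_removal"] = step3

    # Step 4: outlier filter on survivors of cluster removal
    keep4, thresholds = outlier_filter(sub, labels, removed_clusters, cfg)
    keep4 = keep4 & ~in_removed
    out_removed = ~keep4 & ~in_removed
    status[alive[out_removed]] = "outlier_removed"
    step4 = masks["cluster_removal"].copy()
    step4[alive[out_removed]] = False
    masks["outlier_filter"] = step4

    # Step 5: doublet scoring on survivors
    surv = np.flatnonzero(step4)
    scorer = doublet_scorer or score_doublets
    doublet_score = np.full(n, np.nan)
    if len(surv) >= 2:
        scores = np.asarray(scorer(matrix.counts[surv], cfg.seed))
        doublet_score[surv] = scores
        keep5 = doublet_filter(scores, cfg)
    else:
        keep5 = np.ones(len(surv), dtype=bool)
    status[surv[~keep5]] = "doublet_removed"
    step5 = masks["outlier_filter"].copy()
    step5[surv[~keep5]] = False
    masks["doublet_filter"] = step5

    report = feature_table.reset_index().copy()
    report["doublet_score"] = doublet_score
    report["cluster"] = cluster_col
    for name in STEP_NAMES:
        report[f"retained_after_{name}"] = masks[name]
    report["status"] = status
    thresholds = dict(thresholds)
    thresholds["removed_clusters"] = sorted(removed_clusters)
    return FilterResult(
        report=report,
        masks=masks,
        applied_thresholds=thresholds,
        config=cfg,
        seed=cfg.seed,
    )
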