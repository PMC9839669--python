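"""Constrained k-means stratification of patients by stress reactivity.

Clustering variables are the baseline-to-stress2 changes in HR and
RRmean, z-transformed.  The number of variables d and clusters k is
constrained by the sample-size rule n >= 10 x d x k; candidate
configurations are clustered with k-means (k-means++ initialisation,
multiple restarts, minimum within-cluster sum of squares kept) and the
configuration with the minimum total WSS is selected.  Selected clusters
are relabelled 1..k by ascending baseline heart rate so reports are
invariant to k-means label permutation, and characterised by ANOVA +
Tukey on questionnaire scores and by a sparse GLS of trajectories
(variable = cluster x time + baseline).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import models

log = logging.getLogger(__name__)

CANDIDATE_VARIABLES = ("delta_rr_mean_s", "delta_hr_bpm")


def z_transform(values) -> np.ndarray:
    """(x - mean) / sample sd; zero-variance input is an error."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-transform needs at least two values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("z-transform undefined for zero-variance input")
    return (x - np.mean(x)) / sd


@dataclass(frozen=True)
class ClusterConfig:
    variables: tuple[str, ...]
    k: int
    n: int
    seed: int = 0
    n_init: int = 100

    @property
    def d(self) -> int:
        return len(self.variables)

    @property
    def feasible(self) -> bool:
        return self.n >= 10 * self.d * self.k


def enumerate_feasible_configs(
    n: int,
    candidate_vars=CANDIDATE_VARIABLES,
    max_k: int = 5,
    mode: str = "paper",
    seed: int = 0,
    n_init: int = 100,
) -> list[ClusterConfig]:
    """Candidate (variables, k) configurations under the n >= 10dk rule.

    ``paper`` mode reproduces the published procedure for n in the
    fifties with two candidate variables: the two-variable k=2 run plus
    each single variable at k=2 and k=3.  ``rule`` mode enumerates every
    variable subset and k <= max_k that satisfies the inequality.
    """
    if n < 20:
        raise ValueError("too few patients for any feasible clustering")
    out: list[ClusterConfig] = []
    if mode == "paper":
        if len(candidate_vars) >= 2 and n >= 10 * 2 * 2:
            out.append(ClusterConfig(tuple(candidate_vars[:2]), 2, n, seed, n_init))
        for v in candidate_vars:
            for k in (2, 3):
                if n >= 10 * k:
                    out.append(ClusterConfig((v,), k, n, seed, n_init))
        return out
    if mode == "rule":
        for d in range(1, len(candidate_vars) + 1):
            for vars_ in itertools.combinations(candidate_vars, d):
                for k in range(2, max_k + 1):
                    if n >= 10 * d * k:
                        out.append(ClusterConfig(tuple(vars_), k, n, seed, n_init))
        return out
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ClusterResult:
    config: ClusterConfig
    assignments: np.ndarray  # cluster labels 1..k per patient
    centroids: np.ndarray  # (k, d), z-space
    wss: float
    sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sizes:
            self.sizes = [
                int((self.assignments == c).sum())
                for c in range(1, self.config.k + 1)
            ]
        if sum(self.sizes) != self.assignments.size:
            raise ValueError("cluster sizes do not sum to n")
        if self.wss < -1e-12:
            raise ValueError("negative within-cluster sum of squares")


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 100,
    config: ClusterConfig | None = None,
) -> ClusterResult:
    """k-means with k-means++ restarts, keeping the minimum-WSS solution.

    Deterministic given the seed.  Labels are ordered by ascending first
    centroid coordinate for stability; semantic relabelling (by baseline
    HR) happens at characterisation time.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(pts)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    cfg = config or ClusterConfig(
        tuple(f"x{j}" for j in range(pts.shape[1])), k, pts.shape[0], seed, n_init
    )
    return ClusterResult(
        config=cfg,
        assignments=relabel[raw],
        centroids=km.cluster_centers_[order],
        wss=float(km.inertia_),
    )


def total_wss(points: np.ndarray, assignments: np.ndarray) -> float:
    """Sum of squared Euclidean distances to assigned cluster means."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    tot = 0.0
    for c in np.unique(assignments):
        sub = pts[assignments == c]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def run_configs(
    reactivity: pd.DataFrame, configs: list[ClusterConfig]
) -> list[ClusterResult]:
    """Cluster the z-transformed reactivity variables under each config."""
    results = []
    for cfg in configs:
        Z = np.column_stack(
            [z_transform(reactivity[v].to_numpy(float)) for v in cfg.variables]
        )
        results.append(kmeans(Z, cfg.k, cfg.seed, cfg.n_init, config=cfg))
    return results


def select_clustering(results: list[ClusterResult]) -> ClusterResult:
    """Minimum total-WSS result; ties broken by smaller d, then smaller k."""
    if not results:
        raise ValueError("no clustering results to select from")
    return min(results, key=lambda r: (r.wss, r.config.d, r.config.k))


def relabel_by_baseline_hr(
    result: ClusterResult, baseline_hr: np.ndarray
) -> ClusterResult:
    """Relabel clusters 1..k by ascending mean baseline heart rate.

    Cluster 1 becomes the least tachycardic (most control-like) group,
    making reports invariant to the k-means label permutation.
    """
    hr = np.asarray(baseline_hr, dtype=float)
    if hr.size != result.assignments.size:
        raise ValueError("baseline HR length does not match assignments")
    k = result.config.k
    means = np.array(
        [hr[result.assignments == c].mean() for c in range(1, k + 1)]
    )
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_assign = relabel[result.assignments - 1]
    return replace(
        result,
        assignments=new_assign,
        centroids=result.centroids[order],
        sizes=[int((new_assign == c).sum()) for c in range(1, k + 1)],
    )


# --------------------------------------------------------------------------
# Characterisation


@dataclass
class ClusterReport:
    questionnaire_tests: pd.DataFrame
    excluded_items: list[str]
    trajectory_fits: dict  # outcome -> GLSFit
    cluster_sizes: list[int]


def _questionnaire_frame(subjects, assignments: dict[str, int]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        if s.id not in assignments:
            continue
        row = {
            "subject_id": s.id,
            "cluster": assignments[s.id],
            "fiq_total": s.fiq_total,
            "pcs": s.pcs,
            "pss": s.pss,
            "stai_a": s.stai_a,
            "stai_b": s.stai_b,
        }
        for item, val in (s.fiq_items or {}).items():
            row[f"fiq_item_{item}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def characterize_clusters(
    subjects,
    result: ClusterResult,
    subject_ids: list[str],
    summaries=None,
    missing_threshold: float = 0.20,
) -> ClusterReport:
    """Compare questionnaire scores across clusters and refit trajectories.

    Questionnaire variables with a missingness fraction above
    ``missing_threshold`` are excluded with a log entry.  If HRV
    summaries are supplied, each outcome is refit with the sparse GLS
    ``variable = cluster x time + baseline`` (cluster 1 reference).
    """
    if any(s == 0 for s in result.sizes):
        raise ValueError("empty cluster")
    assignments = dict(zip(subject_ids, result.assignments.tolist()))
    qf = _questionnaire_frame(
        [s for s in subjects if s.id in assignments], assignments
    )
    excluded: list[str] = []
    test_rows = []
    variables = [c for c in qf.columns if c not in ("subject_id", "cluster")]
    for var in variables:
        vals = qf[var]
        frac_missing = float(vals.isna().mean())
        if frac_missing > missing_threshold:
            excluded.append(var)
            log.info("variable %s excluded (%.0f%% missing)", var, 100 * frac_missing)
            continue
        sub = qf.dropna(subset=[var])
        try:
            tests = models.anova_tukey(sub[var].to_numpy(float),
                                       sub["cluster"].to_numpy())
        except ValueError:
            continue
        for t in tests:
            test_rows.append(
                {
                    "variable": var,
                    "method": t.method,
                    "statistic": t.statistic,
                    "p": t.p,
                    **{k: str(v) for k, v in t.detail.items()},
                }
            )
    fits: dict = {}
    if summaries is not None:
        cluster_subjects = []
        for s in subjects:
            if s.id in assignments:
                c = replace_cluster(s, assignments[s.id])
                cluster_subjects.append(c)
        for outcome in ("hr_bpm", "rr_mean_s", "rmssd_s", "sdnn_s"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                long = models.build_long_table(
                    summaries, cluster_subjects, outcome, group_attr="cluster_label"
                )
            if long.empty:
                continue
            fits[outcome] = models.fit_gls(long, reference_group="cluster1")
    return ClusterReport(
        questionnaire_tests=pd.DataFrame(test_rows),
        excluded_items=excluded,
        trajectory_fits=fits,
        cluster_sizes=result.sizes,
    )


def replace_cluster(subject, cluster: int):
    """Shallow copy of a subject carrying a ``cluster_label`` attribute."""
    import copy

    s = copy.copy(subject)
    s.cluster_label = f"cluster{cluster}"
    return s
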