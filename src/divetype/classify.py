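"""Dive-type discovery and classification.

The transformed metric table is centered and scaled to unit variance, an
eigendecomposition of its correlation structure retains the smallest number
of principal components whose cumulative explained variance reaches a target
(default 85%), and the retained scores are clustered agglomeratively with
Ward's minimum-variance criterion under Euclidean distance.  Cluster
stability is assessed by bootstrap resampling: each original cluster is
matched to its best Jaccard partner among the clusters of a re-clustered
resample, and the per-cluster Jaccard similarities are averaged over
iterations.

Clusters are then named by a transparent decision list over per-cluster
medians (shallow vs deep at 30 m; short vs long shallow dives at 5 min;
benthic when the median distance to the seafloor is under 25 m; V-shaped
when the bottom fraction is small; Variable when the bottom-phase depth is
highly variable; otherwise Mid-water).  Dives known only from satellite
summaries (max depth + duration) are classified by whether both values fall
inside a type's interquartile window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

TYPE_NAMES = ["Mid-water", "Short-shallow", "V-shaped", "Benthic", "Variable",
              "Long-shallow"]

__all__ = [
    "TYPE_NAMES", "NamingThresholds", "DiveTypeModel",
    "standardize_and_pca", "ward_cluster", "bootstrap_jaccard",
    "assign_type_names", "build_type_quantiles", "classify_summary_dive",
    "classify_summary_dives", "fit_dive_type_model",
]


@dataclass(frozen=True)
class NamingThresholds:
    """Median-based cutoffs for the cluster-naming decision list.

    Units: shallow_max_depth_m (m), short_duration_min (min),
    benthic_dist_m (m), v_bottom_fraction (unitless), variable_sd_m (m).
    Naming is a labeling convenience applied after clustering, not part of
    the clustering itself.
    """

    shallow_max_depth_m: float = 30.0
    short_duration_min: float = 5.0
    benthic_dist_m: float = 25.0
    v_bottom_fraction: float = 0.3
    variable_sd_m: float = 40.0


@dataclass
class DiveTypeModel:
    """Everything needed to reproduce and apply a fitted dive typing.

    Standardization (per-column mean/sd of the transformed metrics), PCA
    loadings and variance fractions, the linkage tree, per-dive labels,
    cluster names, and per-type (Q1, median, Q3) of raw MaxDepth and
    DiveDur for summary-dive classification.
    """

    columns: list
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (n_vars, k)
    variance_fractions: np.ndarray  # all n_vars components
    n_components: int
    linkage_matrix: Optional[np.ndarray] = None
    k_clusters: int = 6
    labels: Optional[np.ndarray] = None
    type_names: Optional[dict] = None
    type_quantiles: Optional[dict] = None

    def to_json(self) -> str:
        d = {
            "columns": list(self.columns),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_components": int(self.n_components),
            "k_clusters": int(self.k_clusters),
            "linkage_matrix": None if self.linkage_matrix is None else self.linkage_matrix.tolist(),
            "labels": None if self.labels is None else np.asarray(self.labels).tolist(),
            "type_names": None if self.type_names is None else {str(k): v for k, v in self.type_names.items()},
            "type_quantiles": self.type_quantiles,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DiveTypeModel":
        d = json.loads(text)
        return cls(
            columns=d["columns"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            variance_fractions=np.asarray(d["variance_fractions"]),
            n_components=d["n_components"],
            linkage_matrix=None if d["linkage_matrix"] is None else np.asarray(d["linkage_matrix"]),
            k_clusters=d["k_clusters"],
            labels=None if d["labels"] is None else np.asarray(d["labels"]),
            type_names=None if d["type_names"] is None else {int(k): v for k, v in d["type_names"].items()},
            type_quantiles=None if d["type_quantiles"] is None else {
                name: {var: tuple(vals) for var, vals in q.items()}
                for name, q in d["type_quantiles"].items()
            },
        )


def standardize_and_pca(table: pd.DataFrame, variance_target: float = 0.85):
    """Center, scale, and project onto the leading principal components.

    Rows with any missing value are excluded (dives lacking neighbors or a
    valid location cannot contribute movement metrics).  Retains the
    smallest k whose cumulative explained variance is >= ``variance_target``.

    Returns ``(scores, model, used_index)`` where ``used_index`` identifies
    the complete rows that entered the analysis.
    """
    complete = table.dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete rows")
    X = complete.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if len(constant):
        names = [complete.columns[i] for i in constant]
        raise ValueError(f"constant column(s) cannot be scaled: {names}")
    Z = (X - means) / sds
    # eigendecomposition of the correlation matrix (Z is standardized)
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    fractions = eigval / eigval.sum()
    cum = np.cumsum(fractions)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(fractions))
    loadings = eigvec[:, :k]
    scores = Z @ loadings
    model = DiveTypeModel(
        columns=list(complete.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        variance_fractions=fractions,
        n_components=k,
    )
    return scores, model, complete.index


def ward_cluster(scores: np.ndarray, k_clusters: int):
    """Ward/Euclidean agglomerative clustering cut at ``k_clusters``.

    Returns ``(labels, linkage_matrix)`` with labels in 0..k-1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = len(scores)
    if k_clusters > n:
        raise ValueError(f"k_clusters={k_clusters} exceeds n={n}")
    Z = linkage(scores, method="ward")
    labels = fcluster(Z, t=k_clusters, criterion="maxclust") - 1
    return labels, Z


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def bootstrap_jaccard(scores: np.ndarray, k_clusters: int, B: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Bootstrap stability of a Ward clustering, clusterboot-style.

    For each of ``B`` resamples (with replacement): re-cluster the resample,
    then match every original cluster to the resample cluster with the
    highest Jaccard similarity over the points present in the resample
    (best match, not a one-to-one assignment).  Returns per-cluster mean
    Jaccard similarity; values near 1 indicate stable clusters, values
    below ~0.6 indicate clusters that dissolve under resampling.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = len(scores)
    rng = np.random.default_rng(seed)
    base_labels, _ = ward_cluster(scores, k_clusters)
    clusters = [set(np.flatnonzero(base_labels == c)) for c in range(k_clusters)]
    sums = np.zeros(k_clusters)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        boot_labels, _ = ward_cluster(scores[idx], k_clusters)
        # map resample clusters back to original point indices (unique points)
        boot_sets = []
        for c in range(k_clusters):
            members = np.unique(idx[boot_labels == c])
            boot_sets.append(set(members.tolist()))
        uniq_set = set(uniq.tolist())
        for c in range(k_clusters):
            present = clusters[c] & uniq_set
            best = max((_jaccard(present, bs) for bs in boot_sets), default=0.0)
            sums[c] += best
    return pd.DataFrame({"cluster": np.arange(k_clusters),
                         "mean_jaccard": sums / B,
                         "n_iterations": B})


def assign_type_names(labels: np.ndarray, raw_metrics: pd.DataFrame,
                      thresholds: NamingThresholds = NamingThresholds()) -> dict:
    """Name each cluster from its raw-metric medians via a decision list.

    Defined for six clusters.  Shallow clusters (median MaxDepth below the
    shallow cutoff) split by duration into Short-shallow / Long-shallow;
    deep clusters are Benthic when near the seafloor, V-shaped when the
    bottom fraction is small, Variable when the bottom-phase depth SD is
    large, and Mid-water otherwise.  If two clusters collide on a name the
    provisional names are returned with a disambiguating suffix so the
    caller can inspect the ambiguity.
    """
    labels = np.asarray(labels)
    sub_all = raw_metrics.reset_index(drop=True)
    names = {}
    for c in np.unique(labels):
        med = sub_all[labels == c].median(skipna=True)
        if med["MaxDepth"] < thresholds.shallow_max_depth_m:
            name = ("Short-shallow" if med["DiveDur"] < thresholds.short_duration_min
                    else "Long-shallow")
        elif med["DistToSeaFlr"] < thresholds.benthic_dist_m:
            name = "Benthic"
        elif med["BottFrac"] <= thresholds.v_bottom_fraction:
            name = "V-shaped"
        elif med["SDBottDepth"] > thresholds.variable_sd_m:
            name = "Variable"
        else:
            name = "Mid-water"
        names[int(c)] = name
    seen: dict = {}
    for c, name in sorted(names.items()):
        if name in seen.values():
            suffix = sum(1 for v in seen.values() if v.startswith(name)) + 1
            names[c] = f"{name} (ambiguous {suffix})"
        seen[c] = names[c]
    return names


def build_type_quantiles(labels: np.ndarray, raw_metrics: pd.DataFrame,
                         type_names: dict) -> dict:
    """Per type: (Q1, median, Q3) of raw MaxDepth and DiveDur.

    Quantiles use linear interpolation between order statistics (the R
    type-7 convention).  A single-member type has Q1 = median = Q3.
    """
    labels = np.asarray(labels)
    quantiles = {}
    for c, name in type_names.items():
        sub = raw_metrics[labels == c]
        quantiles[name] = {
            var: tuple(float(q) for q in np.quantile(sub[var].dropna(), [0.25, 0.5, 0.75]))
            for var in ("MaxDepth", "DiveDur")
        }
    return quantiles


def classify_summary_dive(max_depth: float, duration: float,
                          type_quantiles: dict) -> tuple[str, int]:
    """Classify a satellite-summarized dive by IQR windows.

    Candidate types are those whose [Q1, Q3] windows contain both the max
    depth and the duration.  No candidate -> "Unknown"; several -> the one
    whose medians are nearest, measured as the sum over the two variables of
    |value - median| / (Q3 - Q1).  Returns (name, n_candidates).
    """
    candidates = []
    for name, q in type_quantiles.items():
        (d1, dm, d3) = q["MaxDepth"]
        (t1, tm, t3) = q["DiveDur"]
        if d1 <= max_depth <= d3 and t1 <= duration <= t3:
            score = 0.0
            for val, (lo, mid, hi) in ((max_depth, (d1, dm, d3)), (duration, (t1, tm, t3))):
                iqr = hi - lo
                score += abs(val - mid) / iqr if iqr > 0 else (0.0 if val == mid else np.inf)
            candidates.append((score, name))
    if not candidates:
        return "Unknown", 0
    candidates.sort()
    return candidates[0][1], len(candidates)


def classify_summary_dives(messages: pd.DataFrame, type_quantiles: dict) -> pd.DataFrame:
    """Vectorized wrapper over :func:`classify_summary_dive` for a message table."""
    rows = [classify_summary_dive(r["max_depth_m"], r["duration_min"], type_quantiles)
            for _, r in messages.iterrows()]
    out = messages.copy()
    out["assigned_type"] = [r[0] for r in rows]
    out["n_candidates"] = [r[1] for r in rows]
    return out


def fit_dive_type_model(transformed: pd.DataFrame, raw_metrics: pd.DataFrame,
                        k_clusters: int = 6, variance_target: float = 0.85,
                        thresholds: NamingThresholds = NamingThresholds()):
    """Full typing fit: PCA -> Ward -> names -> quantiles.

    ``transformed`` and ``raw_metrics`` must be row-aligned.  Returns
    ``(model, used_index)``; the model carries labels for the complete rows
    only.
    """
    scores, model, used = standardize_and_pca(transformed, variance_target)
    labels, Z = ward_cluster(scores, k_clusters)
    raw_used = raw_metrics.loc[used].reset_index(drop=True)
    names = assign_type_names(labels, raw_used, thresholds)
    model.linkage_matrix = Z
    model.k_clusters = k_clusters
    model.labels = labels
    model.type_names = names
    model.type_quantiles = build_type_quantiles(labels, raw_used, names)
    return model, used
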