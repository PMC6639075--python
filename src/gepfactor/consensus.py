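"""Consensus step: outlier filtering, clustering, median merge, usage refit.

Replicate components that do not recur across runs (high mean Euclidean
distance to their L = round(rho * R) nearest neighbors in the stack) are
discarded; the survivors are clustered with KMeans into K groups; each group
collapses to its per-gene median; the merged spectra are l1-normalized and
usages are refit per cell by non-negative least squares.  Finally the
programs can be re-expressed in TPM units over all genes by a per-gene NNLS
against the normalized usages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .factorize import ReplicateStack

__all__ = [
    "ConsensusResult",
    "knn_distances",
    "knn_outlier_filter",
    "auto_tau",
    "cluster_and_merge",
    "nnls_rows",
    "refit_usage",
    "refit_spectra_tpm",
    "build_consensus",
]


@dataclass
class ConsensusResult:
    spectra_l1: pd.DataFrame        # K x H, rows sum to 1 (G~(c))
    usage: pd.DataFrame             # cells x K, raw NNLS coefficients (U(c))
    usage_norm: pd.DataFrame        # cells x K, rows sum to 1 (U~(c))
    spectra_tpm: pd.DataFrame | None  # K x all genes (G(TPM))
    knn_distance: np.ndarray        # per stacked component, mean KNN distance
    kept_mask: np.ndarray           # which stacked components survived tau
    cluster_labels: np.ndarray      # KMeans label per surviving component
    rho: float
    tau: float
    K: int
    R: int


def knn_distances(components: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Mean Euclidean distance from each row to its L nearest other rows."""
    if n_neighbors < 1:
        raise ValueError("need at least one neighbor (round(rho*R) >= 1)")
    if n_neighbors > components.shape[0] - 1:
        raise ValueError("more neighbors requested than available components")
    d = cdist(components, components)
    np.fill_diagonal(d, np.inf)  # a component is not its own neighbor
    d.partition(n_neighbors - 1, axis=1)
    return d[:, :n_neighbors].mean(axis=1)


def knn_outlier_filter(stack: ReplicateStack, rho: float,
                       tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Keep components whose mean distance to their round(rho*R) nearest
    neighbors is strictly below tau.  Returns (kept_mask, distances)."""
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    n_neighbors = round(rho * stack.R)
    dist = knn_distances(stack.components, max(n_neighbors, 1))
    kept = dist < tau
    if not kept.any():
        raise ValueError(
            f"tau={tau} filtered out all {dist.size} components; inspect the "
            "distance histogram and raise tau"
        )
    return kept, dist


def auto_tau(distances: np.ndarray) -> float:
    """Knee of the sorted distance curve (max perpendicular distance to the
    chord), the 'truncate the long tail' heuristic for choosing tau."""
    d = np.sort(np.asarray(distances, dtype=float))
    n = d.size
    if n < 3 or d[-1] == d[0]:
        return float(d[-1] * 2 + 1e-12)
    x = np.linspace(0.0, 1.0, n)
    y = (d - d[0]) / (d[-1] - d[0])
    gap = x - y  # distance to the identity chord (up to sqrt 2 factor)
    knee = int(np.argmax(gap))
    if knee >= n - 1:
        return float(d[-1] * (1 + 1e-9) + 1e-12)
    # threshold sits between the knee and the start of the tail, so the
    # strict < comparison keeps the bulk
    return float((d[knee] + d[knee + 1]) / 2)


def cluster_and_merge(components: np.ndarray, K: int, seed: int = 0,
                      n_init: int = 10, max_retries: int = 3
                      ) -> tuple[np.ndarray, np.ndarray]:
    """KMeans (Euclidean) into K clusters, then per-cluster per-gene median,
    rows l1-normalized.  Returns (spectra_l1, labels)."""
    if components.shape[0] < K:
        raise ValueError(
            f"only {components.shape[0]} components survived filtering but "
            f"K={K} clusters requested"
        )
    labels = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=K, n_init=n_init, random_state=seed + attempt)
        labels = km.fit_predict(components)
        if np.unique(labels).size == K:
            break
    else:
        raise RuntimeError("KMeans returned an empty cluster repeatedly")
    merged = np.vstack([
        np.median(components[labels == k], axis=0) for k in range(K)
    ])
    sums = merged.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("a merged spectrum is non-positive; cannot l1-normalize")
    return merged / sums, labels


def nnls_rows(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min ||targets[i] - design @ x||_2 s.t. x >= 0 for each row of
    ``targets``; returns coefficients with one row per target row."""
    out = np.empty((targets.shape[0], design.shape[1]))
    for i in range(targets.shape[0]):
        out[i], _ = nnls(design, targets[i])
    return out


def refit_usage(norm: pd.DataFrame,
                spectra_l1: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell NNLS of the normalized expression profile onto the consensus
    spectra; returns (usage, row-normalized usage).  All-zero refits are kept
    as zeros (with a warning) rather than inventing usage."""
    x = norm.to_numpy(dtype=float)
    g = spectra_l1.to_numpy(dtype=float)
    u = nnls_rows(g.T, x)
    sums = u.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        warnings.warn(f"{int((sums == 0).sum())} cell(s) have all-zero usage")
    u_norm = np.divide(u, sums, out=np.zeros_like(u), where=sums > 0)
    cols = spectra_l1.index
    return (pd.DataFrame(u, index=norm.index, columns=cols),
            pd.DataFrame(u_norm, index=norm.index, columns=cols))


def refit_spectra_tpm(tpm: pd.DataFrame,
                      usage_norm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene NNLS of the TPM profile onto the normalized usages, giving
    programs in TPM units over all genes (including count-filtered ones)."""
    u = usage_norm.to_numpy(dtype=float)
    t = tpm.to_numpy(dtype=float)
    g = nnls_rows(u, t.T)  # genes x K
    return pd.DataFrame(g.T, index=usage_norm.columns, columns=tpm.columns)


def build_consensus(stack: ReplicateStack, norm: pd.DataFrame,
                    tpm: pd.DataFrame | None = None, *, rho: float = 0.3,
                    tau: float | str = "auto",
                    kmeans_seed: int = 0) -> ConsensusResult:
    """Full consensus pass over a replicate stack.

    ``tau`` may be a distance threshold or ``"auto"`` (knee of the sorted
    KNN-distance curve).  ``tpm`` is optional; without it the TPM-unit
    spectra are skipped.
    """
    n_neighbors = max(round(rho * stack.R), 1)
    dist = knn_distances(stack.components, n_neighbors)
    tau_val = auto_tau(dist) if tau == "auto" else float(tau)
    kept = dist < tau_val
    if not kept.any():
        raise ValueError(f"tau={tau_val} filtered out all components")
    spectra, labels = cluster_and_merge(stack.components[kept], stack.K,
                                        seed=kmeans_seed)
    spectra_df = pd.DataFrame(
        spectra, columns=stack.gene_names,
        index=pd.Index([f"GEP_{k}" for k in range(stack.K)], name="program"),
    )
    usage, usage_norm = refit_usage(norm, spectra_df)
    spectra_tpm = refit_spectra_tpm(tpm, usage_norm) if tpm is not None else None
    return ConsensusResult(
        spectra_l1=spectra_df, usage=usage, usage_norm=usage_norm,
        spectra_tpm=spectra_tpm, knn_distance=dist, kept_mask=kept,
        cluster_labels=labels, rho=rho, tau=tau_val, K=stack.K, R=stack.R,
    )
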