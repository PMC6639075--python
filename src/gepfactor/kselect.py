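"""Diagnostics for choosing the number of components K.

Two advisory plots, never an automatic choice: (1) solution stability
(mean silhouette of the stacked l2-normalized replicate components under
their KMeans labels) against the Frobenius reconstruction error of the
consensus solution, per K — the error is computed *without* outlier
filtering; (2) the PCA scree (fraction of variance per principal component)
of the normalized matrix, since the number of NMF components is bounded
below by the linear dimensionality of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .consensus import cluster_and_merge, refit_usage
from .factorize import run_replicates

__all__ = ["KDiagnostics", "stability_error_curve", "pca_scree"]


@dataclass
class KDiagnostics:
    k_values: list[int]
    silhouette: list[float]
    frobenius_error: list[float]
    pca_variance_fraction: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "K": self.k_values,
            "silhouette": self.silhouette,
            "frobenius_error": self.frobenius_error,
        })


def stability_error_curve(norm: pd.DataFrame, k_values: Sequence[int],
                          R: int = 20, base_seed: int = 0) -> KDiagnostics:
    """Stability (silhouette) and consensus reconstruction error per K.

    For each K the full replicate stack is clustered with no tau filtering;
    silhouette uses the Euclidean metric on the l2-normalized components,
    and the error is ||C~ - U(c) G~(c)||_F after the NNLS usage refit.
    """
    sils, errs = [], []
    x = norm.to_numpy(dtype=float)
    for k in k_values:
        if k < 2:
            raise ValueError("K values must be >= 2")
        stack = run_replicates(norm, K=k, R=R, base_seed=base_seed)
        spectra, labels = cluster_and_merge(stack.components, k)
        sils.append(float(silhouette_score(
            stack.components, labels, metric="euclidean")))
        spectra_df = pd.DataFrame(spectra, columns=stack.gene_names)
        usage, _ = refit_usage(norm, spectra_df)
        recon = usage.to_numpy() @ spectra
        errs.append(float(np.linalg.norm(x - recon)))
    return KDiagnostics(
        k_values=list(k_values), silhouette=sils, frobenius_error=errs,
        pca_variance_fraction=pca_scree(norm),
    )


def pca_scree(norm: pd.DataFrame) -> np.ndarray:
    """Fraction of variance per principal component (PCA centers the data
    internally; the NMF input itself is never centered)."""
    x = norm.to_numpy(dtype=float)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    return PCA(n_components=n_comp).fit(x).explained_variance_ratio_
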