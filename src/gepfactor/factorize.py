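"""Replicated NMF runs on the variance-scaled matrix.

Each replicate solves ``min ||C~ - U G||_F`` with non-negativity on both
factors, random initialization, a stopping tolerance of 1e-4 and at most 400
iterations (coordinate descent).  Components are row-l2-normalized and
stacked vertically across replicates; the stack is the input to the
consensus step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = ["ReplicateStack", "run_nmf_replicate", "run_replicates", "loss_trace"]

NMF_TOL = 1e-4
NMF_MAX_ITER = 400


@dataclass
class ReplicateStack:
    """Vertical stack of l2-normalized components from R NMF replicates."""

    components: np.ndarray       # (R*K, H), rows l2-normalized (or all-zero)
    usages: list[np.ndarray]     # R matrices, cells x K
    seeds: list[int]
    K: int
    R: int
    losses: list[float]          # per-replicate Frobenius reconstruction error
    n_iters: list[int]
    gene_names: list[str]

    def replicate_components(self, r: int) -> np.ndarray:
        return self.components[r * self.K:(r + 1) * self.K]


def _as_array(norm) -> tuple[np.ndarray, list[str]]:
    if isinstance(norm, pd.DataFrame):
        return norm.to_numpy(), list(norm.columns)
    arr = np.asarray(norm)
    return arr, [f"g{j}" for j in range(arr.shape[1])]


def l2_normalize_rows(g: np.ndarray) -> np.ndarray:
    """Rows scaled to unit l2 norm; all-zero rows are left as zeros (they are
    removed later by the consensus outlier filter)."""
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    if (norms == 0).any():
        warnings.warn("NMF produced all-zero component row(s); kept as zeros")
    return np.divide(g, norms, out=np.zeros_like(g, dtype=float),
                     where=norms > 0)


def run_nmf_replicate(norm, K: int, seed: int, *, max_iter: int = NMF_MAX_ITER,
                      dtype=np.float32) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One seeded NMF fit. Returns (usage U, components G, loss, n_iter).

    ``G`` is returned in solver units (not yet l2-normalized).  The input is
    cast to ``dtype`` (float32 by default) for speed; the fit is
    deterministic given the seed.
    """
    x, _ = _as_array(norm)
    if np.isnan(x).any():
        raise ValueError("NaN in the normalized matrix")
    if K < 1:
        raise ValueError("K must be >= 1")
    model = NMF(n_components=K, init="random", tol=NMF_TOL, max_iter=max_iter,
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        u = model.fit_transform(np.ascontiguousarray(x, dtype=dtype))
    return (u.astype(float), model.components_.astype(float),
            float(model.reconstruction_err_), int(model.n_iter_))


def run_replicates(norm, K: int, R: int, base_seed: int = 0,
                   dtype=np.float32) -> ReplicateStack:
    """R independently seeded replicates (seed = base_seed + r), components
    l2-normalized and stacked in replicate order."""
    if K < 2:
        raise ValueError("consensus factorization requires K >= 2")
    if R < 1:
        raise ValueError("R must be >= 1")
    _, gene_names = _as_array(norm)
    comps, usages, seeds, losses, iters = [], [], [], [], []
    for r in range(R):
        seed = base_seed + r
        u, g, loss, n_iter = run_nmf_replicate(norm, K, seed, dtype=dtype)
        comps.append(l2_normalize_rows(g))
        usages.append(u)
        seeds.append(seed)
        losses.append(loss)
        iters.append(n_iter)
    return ReplicateStack(
        components=np.vstack(comps), usages=usages, seeds=seeds, K=K, R=R,
        losses=losses, n_iters=iters, gene_names=gene_names,
    )


def loss_trace(norm, K: int, seed: int, checkpoints=(1, 2, 5, 10, 25, 50, 100,
                                                     200, 400)) -> list[float]:
    """Frobenius loss along one replicate's optimization path.

    The seeded solver is deterministic, so refitting with increasing
    iteration caps reconstructs the loss at successive points of the same
    trajectory; the sequence must be non-increasing.
    """
    out = []
    for it in checkpoints:
        _, _, loss, _ = run_nmf_replicate(norm, K, seed, max_iter=it,
                                          dtype=np.float64)
        out.append(loss)
    return out
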