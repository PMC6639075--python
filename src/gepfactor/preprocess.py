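"""Count filtering, over-dispersed gene selection, variance scaling, and TPM.

The factorization input is deliberately *not* log-transformed, not centered,
and not per-cell normalized: genes are selected for over-dispersion first and
then each selected gene column is divided by its sample standard deviation,
so every gene contributes comparable variance while non-negativity is
preserved.  The TPM matrix is computed over **all** genes, including those
that were filtered out of the count matrix, so that final program estimates
can be expressed for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PreprocessResult",
    "filter_cells_genes",
    "v_scores",
    "select_overdispersed",
    "variance_scale",
    "compute_tpm",
    "preprocess",
]

MIN_CELL_COUNTS = 1000     # cells below this total-UMI threshold are removed
DETECTION_RATE = 1 / 500   # genes must be detected in >= ceil(n/500) cells
DEFAULT_H = 2000


@dataclass
class PreprocessResult:
    filtered_counts: pd.DataFrame   # cells x retained genes (C)
    norm_matrix: pd.DataFrame       # cells x H, unit-variance columns (C tilde)
    overdispersed_genes: list[str]  # the H selected genes, input column order
    gene_sd: pd.Series              # sample sd of each over-dispersed gene
    tpm: pd.DataFrame               # cells x all genes, rows sum to 1e6 (T)


def filter_cells_genes(raw: pd.DataFrame) -> pd.DataFrame:
    """Remove cells with < 1000 total UMIs, then genes detected (count > 0)
    in fewer than ceil(n_cells / 500) of the remaining cells."""
    cell_ok = raw.sum(axis=1) >= MIN_CELL_COUNTS
    if not cell_ok.any():
        raise ValueError(
            "cell filter removed every cell (all totals < "
            f"{MIN_CELL_COUNTS} UMIs)"
        )
    kept = raw.loc[cell_ok]
    min_cells = int(np.ceil(kept.shape[0] * DETECTION_RATE))
    gene_ok = (kept > 0).sum(axis=0) >= min_cells
    if not gene_ok.any():
        raise ValueError(
            f"gene detection filter (>= {min_cells} cells) removed every gene"
        )
    return kept.loc[:, gene_ok]


def _running_percentile(x: np.ndarray, y: np.ndarray, pct: float = 33.0,
                        n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x)
    x, y = x[order], y[order]
    dx = (x[-1] - x[0]) / n_bins
    centers = np.linspace(x[0] + dx / 2, x[-1] - dx / 2, n_bins)
    out = np.full(n_bins, np.nan)
    for i, c in enumerate(centers):
        sel = (x >= c - dx / 2) & (x < c + dx / 2)
        if sel.any():
            out[i] = np.percentile(y[sel], pct)
    ok = ~np.isnan(out)
    return centers[ok], out[ok]


def v_scores(counts: pd.DataFrame) -> pd.Series:
    """Above-Poisson dispersion statistic per gene.

    The Fano factor F = var/mean of a gene sampled with Poisson noise on top
    of biological variability follows F = (1+a)(1+b) + b*mu under a null
    CV^2 = a/mu + b relationship.  The null is fitted from running
    33rd-percentile points of log(F/mu) versus log(mu) — the seed for the
    multiplicative constant comes from the histogram mode of log F, and b is
    fitted with a robust cubic loss — and each gene is scored as
    F / ((1+a)(1+b) + b*mu).  Genes with zero mean score -inf.
    """
    x = counts.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    var = x.var(axis=0, ddof=0)
    score = np.full(mu.shape, -np.inf)
    pos = mu > 0
    ff = var[pos] / mu[pos]
    xb, yb = _running_percentile(np.log(mu[pos]), np.log(ff / mu[pos]))
    hist, edges = np.histogram(np.log(ff[ff > 0]), bins=200)
    mode = edges[:-1][np.argmax(hist)] + (edges[1] - edges[0]) / 2
    c = max(np.exp(mode), 1.0)

    def err(b2):
        return np.sum(np.abs(np.log(c * np.exp(-xb) + b2) - yb) ** 3)

    b = float(optimize.fmin(err, x0=0.1, disp=False)[0])
    a = c / (1 + b) - 1
    score[pos] = ff / ((1 + a) * (1 + b) + b * mu[pos])
    return pd.Series(score, index=counts.columns, name="v_score")


def fano_factors(counts: pd.DataFrame) -> pd.Series:
    """Plain variance/mean ratio; transparent fallback ranking."""
    x = counts.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    out = np.where(mu > 0, var / np.where(mu > 0, mu, 1.0), -np.inf)
    return pd.Series(out, index=counts.columns, name="fano")


def select_overdispersed(counts: pd.DataFrame, n_genes: int = DEFAULT_H,
                         method: str = "vscore"
                         ) -> tuple[list[str], pd.Series]:
    """Pick the ``n_genes`` most over-dispersed genes.

    Ties at the selection boundary are broken by gene name so the result is
    deterministic.  Returns (selected gene names in input column order,
    per-gene scores).
    """
    if n_genes < 1:
        raise ValueError("need at least 1 over-dispersed gene")
    if n_genes > counts.shape[1]:
        raise ValueError(
            f"requested {n_genes} genes but only {counts.shape[1]} available"
        )
    if method == "vscore":
        scores = v_scores(counts)
    elif method == "fano":
        scores = fano_factors(counts)
    else:
        raise ValueError(f"unknown over-dispersion method: {method!r}")
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    # lexicographic tie-break at the boundary
    order = pd.DataFrame({"s": -ranked.to_numpy(), "g": ranked.index})
    order = order.sort_values(["s", "g"], kind="mergesort")
    chosen = set(order["g"].head(n_genes))
    selected = [g for g in counts.columns if g in chosen]
    return selected, scores


def variance_scale(counts: pd.DataFrame,
                   genes: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each selected gene column by its sample standard deviation
    (n-1 denominator).  No centering, no log, no per-cell normalization."""
    sub = counts.loc[:, genes].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(
            "zero-variance gene(s) cannot be variance-scaled; remove them "
            f"first: {bad[:10]}"
        )
    norm = pd.DataFrame(sub / sd, index=counts.index, columns=genes)
    return norm, pd.Series(sd, index=genes, name="gene_sd")


def compute_tpm(all_genes_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell's counts to sum to 1e6, over all genes (including
    genes that fail the detection filter)."""
    totals = all_genes_counts.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("cell(s) with zero total counts cannot be TPM-scaled")
    return all_genes_counts.astype(float).div(totals, axis=0) * 1e6


def preprocess(raw: pd.DataFrame, n_overdispersed: int = DEFAULT_H,
               method: str = "vscore",
               from_tpm: bool = False) -> PreprocessResult:
    """Fixed pipeline: filter -> select over-dispersed -> variance scale.

    ``from_tpm=True`` is the full-transcript path: selection and scaling run
    on the TPM matrix of the retained genes instead of raw counts (depth is
    then no longer informative and must be normalized away).
    """
    filtered = filter_cells_genes(raw)
    tpm = compute_tpm(raw.loc[filtered.index])
    source = tpm.loc[:, filtered.columns] if from_tpm else filtered
    genes, _ = select_overdispersed(source, n_overdispersed, method=method)
    norm, sd = variance_scale(source, genes)
    return PreprocessResult(
        filtered_counts=filtered, norm_matrix=norm,
        overdispersed_genes=genes, gene_sd=sd, tpm=tpm,
    )
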