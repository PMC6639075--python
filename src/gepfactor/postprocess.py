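"""Marker-gene association and geneset enrichment.

Marker genes are found by one multivariate ordinary-least-squares regression
per gene: z-scored TPM expression against the **un-normalized** consensus
usage matrix.  A coefficient beta_kj reads as "by how many standard
deviations gene j's expression increases per additional count of usage of
program k".  With an indicator (hard-clustering) usage matrix this reduces
exactly to cluster-mean z-scores.  P-values of the regression are never
used (expression residuals are not normal); geneset enrichment instead runs
a one-sided Mann-Whitney U test on the coefficients, after flooring
negative coefficients at zero so that genes outside the program do not
drive the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MarkerTable", "marker_regression", "geneset_enrichment",
           "enrichment_table"]


@dataclass
class MarkerTable:
    beta: pd.DataFrame        # K x M regression coefficients
    gene_mean: pd.Series      # mu_j of TPM
    gene_sd: pd.Series        # sigma_j of TPM (ddof=1)
    excluded_genes: list[str]  # zero-variance genes, no coefficient defined


def marker_regression(tpm: pd.DataFrame, usage: pd.DataFrame) -> MarkerTable:
    """OLS of z-scored TPM on the un-normalized usage matrix.

    Solved for all genes at once via a least-squares solve; a rank-deficient
    usage matrix falls back to the minimum-norm solution with a warning.
    No intercept: z-scoring already removes each gene's mean.
    """
    t = tpm.to_numpy(dtype=float)
    u = usage.to_numpy(dtype=float)
    mu = t.mean(axis=0)
    sd = t.std(axis=0, ddof=1)
    ok = sd > 0
    excluded = [g for g, keep in zip(tpm.columns, ok) if not keep]
    z = (t[:, ok] - mu[ok]) / sd[ok]
    if np.linalg.matrix_rank(u) < u.shape[1]:
        warnings.warn("usage matrix is rank-deficient; minimum-norm solution")
    beta, *_ = np.linalg.lstsq(u, z, rcond=None)
    beta_df = pd.DataFrame(beta, index=usage.columns,
                           columns=tpm.columns[ok])
    return MarkerTable(
        beta=beta_df,
        gene_mean=pd.Series(mu, index=tpm.columns, name="tpm_mean"),
        gene_sd=pd.Series(sd, index=tpm.columns, name="tpm_sd"),
        excluded_genes=excluded,
    )


def geneset_enrichment(beta_k: pd.Series,
                       geneset: Iterable[str]) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of a geneset's coefficients against the
    rest (alternative: geneset greater), with tie correction.

    Negative coefficients are floored at zero before ranking, so the test is
    insensitive to variation among genes that are simply *not* part of the
    program.  Returns (U statistic, one-sided p-value).
    """
    genes = set(geneset)
    in_set = beta_k.index.isin(genes)
    if not in_set.any():
        raise ValueError("geneset shares no genes with the coefficient vector")
    if in_set.all():
        raise ValueError("geneset covers every scored gene; no background")
    vals = np.maximum(beta_k.to_numpy(dtype=float), 0.0)
    a, b = vals[in_set], vals[~in_set]
    if np.all(vals == vals[0]):
        # complete tie: no evidence either way
        return float(a.size * b.size / 2.0), 0.5
    res = stats.mannwhitneyu(a, b, alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


def enrichment_table(markers: MarkerTable,
                     genesets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Enrichment of each geneset in each program.

    Raw one-sided p-values as in the method, plus a clearly-labelled
    Benjamini-Hochberg column (across genesets within each program) as an
    extra convenience.
    """
    rows = []
    for prog in markers.beta.index:
        beta_k = markers.beta.loc[prog]
        ps = []
        for name, genes in genesets.items():
            u, p = geneset_enrichment(beta_k, genes)
            rows.append({"program": prog, "geneset": name,
                         "U": u, "p_value": p})
            ps.append(p)
        bh = stats.false_discovery_control(ps, method="bh")
        for r, q in zip(rows[-len(ps):], bh):
            r["bh_fdr"] = float(q)
    return pd.DataFrame(rows)
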