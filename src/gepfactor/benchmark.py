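"""Evaluation of GEP recovery against simulation ground truth, plus the
comparison baselines: consensus ICA and ground-truth hard clustering.

Inferred programs are matched to true programs by maximum Pearson
correlation computed over the over-dispersed gene set, with the true
programs expressed in the same units as the factorization input (each gene
divided by its sample standard deviation).  Gene-level accuracy uses an
ROC-style curve of sensitivity against false discovery rate obtained by
sweeping a threshold on the marker-regression coefficients: a gene counts
as truly associated with a program when its ground-truth fold-change is
>= 2, truly unassociated when the fold-change is exactly 1, and is ignored
in between.  Cell-level accuracy thresholds the normalized activity usage
at 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA

from .consensus import (ConsensusResult, build_consensus, cluster_and_merge,
                        knn_distances, refit_usage)
from .factorize import ReplicateStack, run_replicates
from .postprocess import marker_regression
from .preprocess import PreprocessResult, preprocess
from .simulate import SimParams, SimTruth, reduced_params, simulate

__all__ = [
    "EvalReport", "truth_in_normalized_units", "match_components",
    "roc_with_fdr", "sensitivity_at_fdr", "classify_activity_cells",
    "consensus_ica", "ground_truth_clustering", "evaluate_run",
    "run_reduced_benchmark",
]

USAGE_THRESHOLD = 0.10      # normalized-usage call threshold for activity cells
FDR_TARGET = 0.05
DETECTION_PEARSON = 0.80    # "activity GEP detected" correlation cutoff
ACTIVITY_CLUSTER_USAGE = 0.40  # ground-truth clustering activity assignment


@dataclass
class EvalReport:
    matching: pd.DataFrame            # per inferred program: truth index + r
    correlation: np.ndarray           # inferred x truth Pearson matrix
    activity_detected: bool
    activity_program: str | None      # name of the matched inferred program
    roc: pd.DataFrame | None          # sensitivity/FDR curve for activity genes
    sensitivity_at_fdr: float | None
    classification: dict | None       # sensitivity/specificity at 10% usage
    usage_correlation: float | None   # Pearson(inferred usage, phi), phi>0 cells
    phi: np.ndarray | None = None     # true phi of expressing cells
    inferred_usage: np.ndarray | None = None


def truth_in_normalized_units(truth: SimTruth, prep: PreprocessResult,
                              gene_index: pd.Index) -> pd.DataFrame:
    """True programs restricted to the over-dispersed genes and divided by
    each gene's sample standard deviation, i.e. the unit system of the
    factorization input."""
    prog = pd.DataFrame(truth.programs, columns=gene_index)
    sub = prog.loc[:, prep.overdispersed_genes]
    return sub / prep.gene_sd


def match_components(inferred: pd.DataFrame,
                     truth_programs: pd.DataFrame
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Map every inferred component to its most-correlated true program
    (with replacement: several components may map to one program)."""
    a = inferred.to_numpy(dtype=float)
    b = truth_programs.to_numpy(dtype=float)
    corr = np.corrcoef(np.vstack([a, b]))[: a.shape[0], a.shape[0]:]
    best = corr.argmax(axis=1)
    table = pd.DataFrame({
        "truth_index": best,
        "pearson": corr[np.arange(a.shape[0]), best],
    }, index=inferred.index)
    return table, corr


def roc_with_fdr(scores: pd.Series | np.ndarray,
                 fold_change: np.ndarray) -> pd.DataFrame:
    """Sensitivity/FDR pairs over all thresholds on the coefficients.

    Positives: fold-change >= 2.  Negatives: fold-change == 1.  Genes with
    1 < fold-change < 2 are excluded from the evaluation.
    """
    s = np.asarray(scores, dtype=float)
    pos = fold_change >= 2
    neg = fold_change == 1
    use = pos | neg
    if not pos.any():
        raise ValueError("no positive genes (fold-change >= 2); "
                         "sensitivity undefined")
    s, y = s[use], pos[use]
    order = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    sens = tp / y.sum()
    fdr = fp / np.arange(1, s.size + 1)
    return pd.DataFrame({"threshold": s[order], "sensitivity": sens,
                         "fdr": fdr})


def sensitivity_at_fdr(roc: pd.DataFrame, target: float = FDR_TARGET) -> float:
    """Sensitivity at the target FDR, linearly interpolated between the
    adjacent achievable points of the curve."""
    fdr = roc["fdr"].to_numpy()
    sens = roc["sensitivity"].to_numpy()
    best = 0.0
    ok = fdr <= target
    if ok.any():
        best = float(sens[ok].max())
    for i in np.flatnonzero((fdr[:-1] <= target) & (fdr[1:] > target)):
        frac = (target - fdr[i]) / (fdr[i + 1] - fdr[i])
        best = max(best, float(sens[i] + frac * (sens[i + 1] - sens[i])))
    return best


def classify_activity_cells(usage_norm: pd.Series | np.ndarray,
                            phi: np.ndarray,
                            threshold: float = USAGE_THRESHOLD) -> dict:
    """Call cells activity-positive when normalized usage >= threshold.

    Returns sensitivity over phi>0 cells, specificity over phi=0 cells, and
    the Pearson correlation of inferred usage with phi among phi>0 cells.
    """
    u = np.asarray(usage_norm, dtype=float)
    expressing = phi > 0
    called = u >= threshold
    sens = float(called[expressing].mean()) if expressing.any() else np.nan
    spec = float((~called[~expressing]).mean()) if (~expressing).any() else np.nan
    r = (float(np.corrcoef(u[expressing], phi[expressing])[0, 1])
         if expressing.sum() > 1 else np.nan)
    return {"sensitivity": sens, "specificity": spec, "usage_pearson": r}


def align_ica_signs(sources: np.ndarray,
                    mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the ICA sign ambiguity: any component whose median usage
    across cells is positive is multiplied by -1 together with its usage,
    so orientations agree across replicates."""
    sources = sources.copy()
    mixing = mixing.copy()
    flip = np.median(sources, axis=0) > 0
    sources[:, flip] *= -1.0
    mixing[flip] *= -1.0
    return sources, mixing


def consensus_ica(norm: pd.DataFrame, K: int, R: int, *, rho: float = 0.3,
                  tau: float | str = "auto", base_seed: int = 0,
                  kmeans_seed: int = 0) -> ConsensusResult:
    """Consensus ICA: R FastICA replicates, sign-aligned, then the same
    consensus machinery as cNMF but with an unconstrained usage refit.

    ICA components have a sign ambiguity; any component whose median usage
    across cells is positive is flipped (together with its usage) so that
    orientations agree across replicates before stacking.
    """
    x = norm.to_numpy(dtype=float)
    comps = []
    for r in range(R):
        ica = FastICA(n_components=K, random_state=base_seed + r)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(x)
        _, mixing = align_ica_signs(sources, ica.mixing_.T)  # K x H spectra
        norms = np.linalg.norm(mixing, axis=1, keepdims=True)
        comps.append(np.divide(mixing, norms, out=np.zeros_like(mixing),
                               where=norms > 0))
    stack = np.vstack(comps)

    n_neighbors = max(round(rho * R), 1)
    dist = knn_distances(stack, n_neighbors)
    from .consensus import auto_tau
    tau_val = auto_tau(dist) if tau == "auto" else float(tau)
    kept = dist < tau_val
    if kept.sum() < K:   # ICA stacks can be more dispersed; fall back to all
        warnings.warn("tau kept fewer than K ICA components; using all")
        kept = np.ones(stack.shape[0], dtype=bool)
    km = KMeans(n_clusters=K, n_init=10, random_state=kmeans_seed)
    labels = km.fit_predict(stack[kept])
    merged = np.vstack([np.median(stack[kept][labels == k], axis=0)
                        for k in range(K)])
    spectra = pd.DataFrame(
        merged, columns=norm.columns,
        index=pd.Index([f"ICA_{k}" for k in range(K)], name="program"))
    # unconstrained least-squares usage (ICA loadings may be negative)
    u, *_ = np.linalg.lstsq(merged.T, x.T, rcond=None)
    usage = pd.DataFrame(u.T, index=norm.index, columns=spectra.index)
    return ConsensusResult(
        spectra_l1=spectra, usage=usage, usage_norm=usage,
        spectra_tpm=None, knn_distance=dist, kept_mask=kept,
        cluster_labels=labels, rho=rho, tau=tau_val, K=K, R=R,
    )


def ground_truth_clustering(tpm: pd.DataFrame, identity: np.ndarray,
                            phi: np.ndarray, n_identity: int
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hard-clustering upper-bound baseline built from ground truth.

    Each cell joins the cluster of its true identity program, except cells
    with more than 40% true activity usage, which join an activity cluster.
    Cluster GEPs are mean TPM vectors; the usage matrix is the indicator
    design, so the marker regression reduces to cluster-mean z-scores.
    """
    k_act = n_identity
    labels = np.where(phi > ACTIVITY_CLUSTER_USAGE, k_act, identity)
    u = np.zeros((tpm.shape[0], n_identity + 1))
    valid = labels >= 0               # doublets carry no identity label
    u[np.flatnonzero(valid), labels[valid].astype(int)] = 1.0
    names = [f"cluster_{k}" for k in range(n_identity)] + ["cluster_activity"]
    usage = pd.DataFrame(u, index=tpm.index, columns=names)
    t = tpm.to_numpy(dtype=float)
    geps = np.vstack([
        t[labels == k].mean(axis=0) if (labels == k).any() else
        np.zeros(t.shape[1]) for k in range(n_identity + 1)
    ])
    return pd.DataFrame(geps, index=names, columns=tpm.columns), usage


def _cell_truth_arrays(truth: SimTruth,
                       cell_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return truth.identity[cell_mask], truth.phi[cell_mask]


def evaluate_run(result: ConsensusResult, prep: PreprocessResult,
                 truth: SimTruth, gene_index: pd.Index,
                 cell_mask: np.ndarray, *,
                 usage_for_regression: pd.DataFrame | None = None,
                 signed: bool = False) -> EvalReport:
    """Score one consensus solution against ground truth.

    ``cell_mask`` marks which simulated cells survived the count filter.
    ``signed=True`` (consensus ICA) orients the matched activity component
    by the sign of its correlation before the ROC sweep.
    """
    truth_norm = truth_in_normalized_units(truth, prep, gene_index)
    corr_spectra = result.spectra_l1
    if signed:
        a = corr_spectra.to_numpy(); b = truth_norm.to_numpy()
        corr = np.corrcoef(np.vstack([a, b]))[: a.shape[0], a.shape[0]:]
        corr = np.abs(corr)
        best = corr.argmax(axis=1)
        matching = pd.DataFrame({"truth_index": best,
                                 "pearson": corr[np.arange(a.shape[0]), best]},
                                index=corr_spectra.index)
    else:
        matching, corr = match_components(corr_spectra, truth_norm)

    act_idx = truth.programs.shape[0] - 1
    act_corr = corr[:, act_idx]
    best_component = int(act_corr.argmax())
    detected = bool(act_corr[best_component] > DETECTION_PEARSON)
    act_name = result.spectra_l1.index[best_component]

    usage = usage_for_regression if usage_for_regression is not None else result.usage
    markers = marker_regression(prep.tpm, usage)
    scores = markers.beta.loc[act_name]
    if signed:
        # re-orient so the activity axis points positive
        raw = np.corrcoef(result.spectra_l1.to_numpy()[best_component],
                          truth_norm.to_numpy()[act_idx])[0, 1]
        scores = scores * np.sign(raw)
    fc_act = pd.Series(truth.de_foldchange[act_idx], index=gene_index)
    roc = roc_with_fdr(scores.reindex(markers.beta.columns),
                       fc_act.reindex(markers.beta.columns).to_numpy())
    sens = sensitivity_at_fdr(roc)

    _, phi = _cell_truth_arrays(truth, cell_mask)
    u_act = result.usage_norm[act_name].to_numpy()
    cls = classify_activity_cells(u_act, phi)
    return EvalReport(
        matching=matching, correlation=corr, activity_detected=detected,
        activity_program=act_name, roc=roc, sensitivity_at_fdr=sens,
        classification=cls, usage_correlation=cls["usage_pearson"],
        phi=phi[phi > 0], inferred_usage=u_act[phi > 0],
    )


def evaluate_clustering_baseline(prep: PreprocessResult, truth: SimTruth,
                                 cell_mask: np.ndarray,
                                 gene_index: pd.Index) -> float:
    """Sensitivity at 5% FDR for the ground-truth hard-clustering baseline,
    scored through the same regression-ROC path as the factorizations."""
    identity, phi = _cell_truth_arrays(truth, cell_mask)
    n_identity = truth.programs.shape[0] - 1
    _, usage = ground_truth_clustering(prep.tpm, identity, phi, n_identity)
    markers = marker_regression(prep.tpm, usage)
    fc_act = pd.Series(truth.de_foldchange[-1], index=gene_index)
    roc = roc_with_fdr(markers.beta.loc["cluster_activity"],
                       fc_act.reindex(markers.beta.columns).to_numpy())
    return sensitivity_at_fdr(roc)


@dataclass
class BenchmarkRun:
    """Everything produced by one reduced-benchmark execution."""
    params: SimParams
    prep: PreprocessResult
    truth: SimTruth
    cell_mask: np.ndarray
    gene_index: pd.Index
    consensus: ConsensusResult
    report: EvalReport


def run_reduced_benchmark(seed: int, *, n_cells: int = 3000,
                          n_genes: int = 5000, activity_n_genes: int = 800,
                          doublet_rate: float = 0.06, de_loc: float = 1.0,
                          H: int = 1000, K: int = 14, R: int = 50,
                          rho: float = 0.3, tau: float | str = 0.03,
                          selection: str = "fano") -> BenchmarkRun:
    """Simulate -> preprocess -> cNMF consensus -> evaluate, at reduced scale.

    The problem size (cells/genes/R/H) is scaled to single-CPU minutes; all
    generative parameters keep their full-scale defaults.  Gene selection
    defaults to the Fano ranking here: with only a few thousand simulated
    genes the v-score's fitted noise baseline is poorly constrained and
    under-ranks the partially-used activity genes (see docs/methods.md).
    """
    params = reduced_params(seed, n_cells=n_cells, n_genes=n_genes,
                            activity_n_genes=activity_n_genes,
                            doublet_rate=doublet_rate, de_loc=de_loc)
    counts, truth = simulate(params)
    prep = preprocess(counts, n_overdispersed=H, method=selection)
    cell_mask = counts.index.isin(prep.filtered_counts.index)
    stack = run_replicates(prep.norm_matrix, K=K, R=R, base_seed=seed * 1000)
    try:
        cons = build_consensus(stack, prep.norm_matrix, prep.tpm,
                               rho=rho, tau=tau)
    except ValueError:
        # a fixed tau can under-keep on an unlucky seed; fall back to the
        # knee heuristic rather than aborting the whole benchmark
        warnings.warn(f"tau={tau} kept fewer than K components; using auto")
        cons = build_consensus(stack, prep.norm_matrix, prep.tpm,
                               rho=rho, tau="auto")
    report = evaluate_run(cons, prep, truth, counts.columns, cell_mask)
    return BenchmarkRun(params=params, prep=prep, truth=truth,
                        cell_mask=cell_mask, gene_index=counts.columns,
                        consensus=cons, report=report)


def evaluate_cica(run: BenchmarkRun, R: int | None = None,
                  tau: float | str = 0.03) -> EvalReport:
    """Consensus-ICA evaluation on an existing benchmark run's inputs."""
    cons = consensus_ica(run.prep.norm_matrix, K=run.consensus.K,
                         R=R or run.consensus.R, rho=run.consensus.rho,
                         tau=tau, base_seed=run.params.seed * 1000 + 500_000)
    return evaluate_run(cons, run.prep, run.truth, run.gene_index,
                        run.cell_mask, signed=True)


def k_robustness(run: BenchmarkRun, k_values: Sequence[int] = (13, 15),
                 pearson: float = 0.70) -> dict[int, int]:
    """Re-factorize an existing benchmark simulation at other K values and
    count how many of the true programs are still matched above the Pearson
    threshold by some consensus component."""
    truth_norm = truth_in_normalized_units(run.truth, run.prep,
                                           run.gene_index)
    out = {}
    for k in k_values:
        stack = run_replicates(run.prep.norm_matrix, K=k,
                               R=run.consensus.R,
                               base_seed=run.params.seed * 1000 + k * 10_000)
        cons = build_consensus(stack, run.prep.norm_matrix,
                               rho=run.consensus.rho, tau=run.consensus.tau)
        _, corr = match_components(cons.spectra_l1, truth_norm)
        out[k] = int((corr.max(axis=0) > pearson).sum())
    return out
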