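"""Shared fixtures.

The heavy benchmark computations are session-scoped and lazily evaluated:
each reduced-scale seed is simulated and factorized at most once, and only
light summaries are kept in memory (the full run object is retained for the
first seed, which several evaluation tests reuse).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message="invalid value encountered")

from gepfactor import SimParams, preprocess, simulate
from gepfactor.benchmark import (evaluate_cica, evaluate_clustering_baseline,
                                 run_reduced_benchmark)

# Reduced-benchmark configuration used by the acceptance-level tests.
# Problem sizes are scaled to single-CPU minutes; generative parameters are
# the full-scale defaults (see docs/methods.md).
BENCH = dict(n_cells=3000, n_genes=5000, activity_n_genes=800,
             doublet_rate=0.06, de_loc=1.0, H=1000, K=14, R=16,
             rho=0.3, tau=0.03)
BENCH_SEEDS = list(range(1, 11))
ORDERING_SEEDS = list(range(1, 6))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but non-trivial simulation for unit-level pipeline tests."""
    params = SimParams(n_cells=400, n_genes=1000, activity_n_genes=200,
                       doublet_rate=0.05, seed=11)
    counts, truth = simulate(params)
    return counts, truth, params


@pytest.fixture(scope="session")
def tiny_prep(tiny_sim):
    counts, _, _ = tiny_sim
    return preprocess(counts, n_overdispersed=300, method="fano")


def _run_benchmark(seed):
    return run_reduced_benchmark(
        seed,
        n_cells=BENCH["n_cells"], n_genes=BENCH["n_genes"],
        activity_n_genes=BENCH["activity_n_genes"],
        doublet_rate=BENCH["doublet_rate"], de_loc=BENCH["de_loc"],
        H=BENCH["H"], K=BENCH["K"], R=BENCH["R"],
        rho=BENCH["rho"], tau=BENCH["tau"],
    )


def _summarize(run, with_baselines):
    rep = run.report
    out = {
        "activity_pearson": float(rep.correlation[:, -1].max()),
        "detected": rep.activity_detected,
        "sens_cnmf": rep.sensitivity_at_fdr,
        "cls_sens": rep.classification["sensitivity"],
        "cls_spec": rep.classification["specificity"],
        "usage_r": rep.usage_correlation,
        "phi": rep.phi,
        "u_act": rep.inferred_usage,
        "recov_08": int((rep.correlation.max(axis=0) > 0.80).sum()),
    }
    if with_baselines:
        ica = evaluate_cica(run)
        out["sens_cica"] = ica.sensitivity_at_fdr
        out["sens_gt"] = evaluate_clustering_baseline(
            run.prep, run.truth, run.cell_mask, run.gene_index)
    return out


class _BenchCache:
    def __init__(self):
        self._summaries = {}
        self._seed1_run = None

    def summary(self, seed):
        if seed not in self._summaries:
            run = _run_benchmark(seed)
            self._summaries[seed] = _summarize(
                run, with_baselines=seed in ORDERING_SEEDS)
            if seed == BENCH_SEEDS[0]:
                self._seed1_run = run   # kept for reuse by other tests
        return self._summaries[seed]

    def seed1_run(self):
        self.summary(BENCH_SEEDS[0])
        return self._seed1_run


@pytest.fixture(scope="session")
def bench_cache():
    return _BenchCache()
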