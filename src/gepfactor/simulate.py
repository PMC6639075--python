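"""Splatter-style scRNA-Seq count simulator with identity programs, one
activity program, and doublets.

The generative model
--------------------
Gene expression programs (GEPs) are vectors of per-gene expression
proportions.  ``n_identity`` identity programs and one activity program are
drawn by the Splatter recipe: gamma base means, lognormal expression-outlier
replacement, and lognormal differential-expression (DE) factors applied to a
random subset of genes per program.  Each cell i is assigned one identity
program I(i) and an activity usage ``phi_i`` (0 for most cells); its mean
expression profile is the mixture

    lambda_i = L_i * (phi_i * Z_a + (1 - phi_i) * Z_I(i))

with lognormal library size ``L_i``.  Gene-level biological overdispersion
(BCV) perturbs the means through a gamma draw whose coefficient of variation
follows a scaled inverse-chi-square trend, and observed counts are Poisson
around the perturbed means.  Doublets are built afterwards by summing two
singlet count vectors and downsampling (without replacement) to the larger
of the two parent totals.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimParams.seed``; given the seed the output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "SimTruth",
    "sample_programs",
    "assign_cells",
    "simulate_counts",
    "make_doublets",
    "simulate",
    "PRESETS",
]

#: Skewed cell-type proportions (neuronal cluster frequencies) used by the
#: variable-proportion simulation preset.  The printed values sum to 1.0003;
#: they are renormalized at draw time.
SKEWED_CELLTYPE_PROBS = (
    0.215, 0.210, 0.195, 0.130, 0.0924, 0.0328, 0.028, 0.0269,
    0.0149, 0.0119, 0.0114, 0.009, 0.009, 0.008, 0.006,
)


@dataclass
class SimParams:
    """Parameters of the simulation.

    Defaults reproduce the benchmark conditions: 13 identity programs plus
    one activity program expressed by 30% of cells of four cell types at a
    usage uniform on [0.1, 0.7], 6% doublets, and Splatter hyperparameters
    fitted to a droplet scRNA-Seq dataset (lib_loc=7.64, lib_scale=0.78,
    mean_rate=7.68, mean_shape=0.34, expout_prob=0.00286, expout_loc=6.15,
    expout_scale=0.49, bcv_dispersion=0.448, bcv_dof=22.087).  ``de_loc``
    sets the signal-to-noise level (location of the lognormal DE factors).
    """

    n_cells: int = 15_000          # singlet cells; doublets are appended
    n_genes: int = 25_000
    n_identity: int = 13
    de_prob: float = 0.025         # P(gene is DE) per identity program
    de_loc: float = 1.0            # lognormal DE-factor location
    de_scale: float = 1.0          # lognormal DE-factor scale
    activity_n_genes: int = 1_000  # genes associated with the activity program
    activity_celltypes: int = 4
    activity_frac: float = 0.30    # fraction of cells of those types expressing it
    activity_usage_low: float = 0.10
    activity_usage_high: float = 0.70
    doublet_rate: float = 0.06
    mean_rate: float = 7.68        # gamma rate of base gene means
    mean_shape: float = 0.34       # gamma shape of base gene means
    lib_loc: float = 7.64          # lognormal library-size location
    lib_scale: float = 0.78
    expout_prob: float = 0.00286   # expression-outlier gene probability
    expout_loc: float = 6.15
    expout_scale: float = 0.49
    bcv_dispersion: float = 0.448  # common biological CV
    bcv_dof: float = 22.087        # inverse-chi-square degrees of freedom
    celltype_probs: Sequence[float] | None = None  # uniform when None
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_prob", "activity_frac", "doublet_rate", "expout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.doublet_rate >= 1.0:
            raise ValueError("doublet_rate must be < 1")
        if self.activity_celltypes > self.n_identity:
            raise ValueError("activity_celltypes cannot exceed n_identity")
        if not self.activity_usage_low < self.activity_usage_high:
            raise ValueError("activity usage bounds must satisfy low < high")
        if self.activity_n_genes > self.n_genes:
            raise ValueError(
                f"activity_n_genes={self.activity_n_genes} exceeds "
                f"n_genes={self.n_genes}"
            )
        if self.celltype_probs is not None:
            p = np.asarray(self.celltype_probs, dtype=float)
            if p.size != self.n_identity:
                raise ValueError("celltype_probs length must equal n_identity")
            if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-3):
                raise ValueError("celltype_probs must be non-negative and sum to 1")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated counts.

    ``identity`` is the identity-program index per cell (-1 for doublets,
    whose parents carry the identities); ``phi`` is the activity usage,
    which is 0 or in [usage_low, usage_high] — doublets carry phi = 0 and
    their activity provenance is recoverable through the parent indices.
    ``programs`` holds the (n_identity + 1) x n_genes true expression
    proportions, activity program last.  ``de_foldchange`` holds the
    per-program, per-gene DE factor (1 for non-DE genes).
    """

    identity: np.ndarray            # (n_cells_total,) int, -1 for doublets
    phi: np.ndarray                 # (n_cells_total,) float
    library_size: np.ndarray        # (n_cells_total,) realized total counts
    is_doublet: np.ndarray          # (n_cells_total,) bool
    doublet_parents: np.ndarray     # (n_cells_total, 2) int, -1 for singlets
    programs: np.ndarray            # (n_identity + 1, n_genes) proportions
    de_foldchange: np.ndarray       # (n_identity + 1, n_genes)
    activity_celltypes: np.ndarray  # identity indices hosting the activity GEP
    n_singlets: int

    @property
    def activity_program(self) -> np.ndarray:
        return self.programs[-1]

    def cell_table(self, cells: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identity": self.identity,
                "phi": self.phi,
                "library_size": self.library_size,
                "is_doublet": self.is_doublet,
                "parent_a": self.doublet_parents[:, 0],
                "parent_b": self.doublet_parents[:, 1],
            },
            index=pd.Index(cells, name="cell"),
        )


def _lognormal_de_factors(rng: np.random.Generator, n: int, loc: float,
                          scale: float) -> np.ndarray:
    # Splatter draws lognormal factors and inverts draws below 1, so with the
    # down-regulation probability at 0 every DE factor is an up-factor >= 1.
    f = rng.lognormal(loc, scale, n)
    f[f < 1.0] = 1.0 / f[f < 1.0]
    return f


def sample_programs(params: SimParams,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the true GEPs and their DE fold-changes.

    Returns ``(programs, de_foldchange)`` where ``programs`` is a
    ``(n_identity + 1, n_genes)`` matrix of expression proportions (rows sum
    to 1, activity program last).
    """
    params.validate()
    m = params.n_genes
    base = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, m)

    # Expression outliers: mean replaced by median * lognormal factor.
    outlier = rng.random(m) < params.expout_prob
    if outlier.any():
        fac = _lognormal_de_factors(
            rng, int(outlier.sum()), params.expout_loc, params.expout_scale
        )
        base[outlier] = np.median(base) * fac

    n_prog = params.n_identity + 1
    fc = np.ones((n_prog, m))
    for k in range(params.n_identity):
        de = rng.random(m) < params.de_prob
        fc[k, de] = _lognormal_de_factors(
            rng, int(de.sum()), params.de_loc, params.de_scale
        )
    # The activity program perturbs an exact number of designated genes.
    act_genes = rng.choice(m, params.activity_n_genes, replace=False)
    fc[-1, act_genes] = _lognormal_de_factors(
        rng, params.activity_n_genes, params.de_loc, params.de_scale
    )

    programs = base * fc
    programs /= programs.sum(axis=1, keepdims=True)
    return programs, fc


def assign_cells(params: SimParams,
                 rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign identities and activity usages to singlet cells.

    Identity ~ multinomial(celltype_probs); within ``activity_celltypes``
    randomly chosen cell types, each cell expresses the activity program
    with probability ``activity_frac`` at a usage uniform on
    [activity_usage_low, activity_usage_high].

    Returns ``(identity, phi, activity_types)``.
    """
    params.validate()
    if params.celltype_probs is None:
        probs = np.full(params.n_identity, 1.0 / params.n_identity)
    else:
        probs = np.asarray(params.celltype_probs, dtype=float)
        probs = probs / probs.sum()
    identity = rng.choice(params.n_identity, size=params.n_cells, p=probs)
    phi = np.zeros(params.n_cells)
    activity_types = rng.permutation(params.n_identity)[: params.activity_celltypes]
    for t in activity_types:
        cells = np.flatnonzero(identity == t)
        chosen = cells[rng.random(cells.size) < params.activity_frac]
        phi[chosen] = rng.uniform(
            params.activity_usage_low, params.activity_usage_high, chosen.size
        )
    return identity, phi, activity_types


def simulate_counts(programs: np.ndarray, identity: np.ndarray,
                    phi: np.ndarray, params: SimParams,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw singlet UMI counts around the mixed per-cell means.

    Per cell: ``lambda_i = L_i (phi_i Z_a + (1-phi_i) Z_I(i))`` with
    L_i ~ lognormal(lib_loc, lib_scale).  BCV perturbation per Splatter:
    ``B_ij = (bcv_dispersion + 1/sqrt(lambda_ij)) * sqrt(dof / chi2_j)``
    with one chi-square draw per gene; the perturbed mean is
    ``Gamma(shape=1/B^2, mean=lambda)`` and counts are Poisson.

    Returns ``(counts, expected_library_size)``.
    """
    n = identity.size
    lib = rng.lognormal(params.lib_loc, params.lib_scale, n)
    chi = rng.chisquare(params.bcv_dof, params.n_genes)
    trend = np.sqrt(params.bcv_dof / chi)

    lam = lib[:, None] * (
        phi[:, None] * programs[-1] + (1.0 - phi[:, None]) * programs[identity]
    )
    if np.isnan(lam).any():
        raise ValueError("NaN in per-cell means; check programs and params")
    bcv = (params.bcv_dispersion + 1.0 / np.sqrt(lam)) * trend[None, :]
    shape = 1.0 / bcv**2
    perturbed = rng.gamma(shape, lam / shape)
    counts = rng.poisson(perturbed)
    return counts, lib


def downsample_counts(vec: np.ndarray, target: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Downsample a count vector to ``target`` total by sampling observed
    molecules without replacement (multivariate hypergeometric); zero entries
    stay zero and expectations are proportional to the input."""
    total = int(vec.sum())
    if target >= total:
        return vec.copy()
    return rng.multivariate_hypergeometric(vec.astype(np.int64), target)


def make_doublets(counts: np.ndarray, truth: SimTruth, rate: float,
                  rng: np.random.Generator
                  ) -> tuple[np.ndarray, SimTruth]:
    """Append doublets so the final doublet fraction equals ``rate``.

    ``round(rate / (1 - rate) * n_singlets)`` doublets are constructed, each
    by sampling two distinct singlets (with replacement across doublets),
    summing their count vectors and downsampling to the larger of the two
    parent totals.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("doublet rate must lie in [0, 1)")
    n_singlets = counts.shape[0]
    n_doublets = round(rate / (1.0 - rate) * n_singlets)
    if n_doublets == 0:
        return counts, truth
    if n_singlets < 2:
        raise ValueError("need at least 2 singlets to form a doublet")

    rows, parents, phis, totals = [], [], [], []
    singlet_totals = counts.sum(axis=1)
    for _ in range(n_doublets):
        a, b = rng.choice(n_singlets, 2, replace=False)
        summed = counts[a] + counts[b]
        target = int(max(singlet_totals[a], singlet_totals[b]))
        vec = downsample_counts(summed, target, rng)
        rows.append(vec)
        parents.append((a, b))
        # doublets carry phi = 0; activity provenance lives in the parents
        phis.append(0.0)
        totals.append(target)

    counts_all = np.vstack([counts, np.array(rows)])
    n_total = counts_all.shape[0]
    identity = np.concatenate([truth.identity, np.full(n_doublets, -1)])
    phi = np.concatenate([truth.phi, np.array(phis)])
    lib = np.concatenate([truth.library_size, np.array(totals, dtype=float)])
    is_dbl = np.zeros(n_total, dtype=bool)
    is_dbl[n_singlets:] = True
    par = np.full((n_total, 2), -1, dtype=int)
    par[n_singlets:] = np.array(parents)

    new_truth = SimTruth(
        identity=identity, phi=phi, library_size=lib, is_doublet=is_dbl,
        doublet_parents=par, programs=truth.programs,
        de_foldchange=truth.de_foldchange,
        activity_celltypes=truth.activity_celltypes,
        n_singlets=n_singlets,
    )
    return counts_all, new_truth


def simulate(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Run the full generator; returns (counts cells x genes, truth)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    programs, fc = sample_programs(params, rng)
    identity, phi, activity_types = assign_cells(params, rng)
    counts, lib = simulate_counts(programs, identity, phi, params, rng)
    truth = SimTruth(
        identity=identity, phi=phi,
        library_size=counts.sum(axis=1).astype(float),
        is_doublet=np.zeros(params.n_cells, dtype=bool),
        doublet_parents=np.full((params.n_cells, 2), -1, dtype=int),
        programs=programs, de_foldchange=fc,
        activity_celltypes=activity_types, n_singlets=params.n_cells,
    )
    counts, truth = make_doublets(counts, truth, params.doublet_rate, rng)
    cells = [f"cell_{i}" for i in range(counts.shape[0])]
    genes = [f"gene_{j}" for j in range(params.n_genes)]
    df = pd.DataFrame(counts, index=pd.Index(cells, name="cell"),
                      columns=pd.Index(genes, name="gene"))
    return df, truth


def _preset(name: str, **overrides) -> SimParams:
    base = {
        "full": {},
        "doublet50": {"doublet_rate": 0.50},
        "skewed": {"celltype_probs": SKEWED_CELLTYPE_PROBS,
                   "n_identity": len(SKEWED_CELLTYPE_PROBS)},
    }[name]
    base.update(overrides)
    return SimParams(**base)


#: Named parameter presets for the CLI and the benchmark harness.
PRESETS = {
    "full": lambda **kw: _preset("full", **kw),
    "doublet50": lambda **kw: _preset("doublet50", **kw),
    "skewed": lambda **kw: _preset("skewed", **kw),
}


def reduced_params(seed: int = 0, *, n_cells: int = 3000, n_genes: int = 5000,
                   activity_n_genes: int = 800, doublet_rate: float = 0.06,
                   de_loc: float = 1.0) -> SimParams:
    """Benchmark conditions scaled to run on a single CPU in minutes.

    Everything except the problem size (cells, genes, activity genes)
    follows the full-scale defaults.
    """
    return SimParams(
        n_cells=n_cells, n_genes=n_genes, activity_n_genes=activity_n_genes,
        doublet_rate=doublet_rate, de_loc=de_loc, seed=seed,
    )
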