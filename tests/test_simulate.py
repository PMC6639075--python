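"""Generator: program sampling, cell assignment, counts, doublets."""

import numpy as np
import pytest

from gepfactor.simulate import (SimParams, SimTruth, assign_cells,
                                downsample_counts, make_doublets,
                                sample_programs, simulate, simulate_counts)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSamplePrograms:
    def test_no_de_makes_identity_programs_equal(self):
        p = SimParams(n_cells=10, n_genes=500, de_prob=0.0,
                      activity_n_genes=50, expout_prob=0.0, seed=1)
        programs, fc = sample_programs(p, _rng(1))
        # all identity programs collapse to the base proportions
        for k in range(1, p.n_identity):
            np.testing.assert_allclose(programs[k], programs[0])
        assert (fc[: p.n_identity] == 1).all()

    def test_de_gene_count_is_binomial(self):
        p = SimParams(n_cells=10, n_genes=25_000, seed=3)
        _, fc = sample_programs(p, _rng(3))
        n_de = (fc[: p.n_identity] != 1).sum(axis=1)
        # expectation 625, +-4 binomial sd each way
        sd = np.sqrt(25_000 * 0.025 * 0.975)
        assert ((n_de > 625 - 4 * sd) & (n_de < 625 + 4 * sd)).all()
        assert (fc[-1] != 1).sum() == p.activity_n_genes

    def test_matches_independent_recipe_transcription(self):
        # independent straight-line transcription of the sampling recipe
        p = SimParams(n_cells=5, n_genes=10, n_identity=2,
                      activity_celltypes=2, activity_n_genes=3,
                      de_prob=0.3, seed=7)
        programs, fc = sample_programs(p, _rng(42))

        r = _rng(42)
        base = r.gamma(p.mean_shape, 1.0 / p.mean_rate, 10)
        out = r.random(10) < p.expout_prob
        if out.any():
            f = r.lognormal(p.expout_loc, p.expout_scale, out.sum())
            f[f < 1] = 1 / f[f < 1]
            base[out] = np.median(base) * f
        exp_fc = np.ones((3, 10))
        for k in range(2):
            de = r.random(10) < p.de_prob
            f = r.lognormal(p.de_loc, p.de_scale, de.sum())
            f[f < 1] = 1 / f[f < 1]
            exp_fc[k, de] = f
        ag = r.choice(10, 3, replace=False)
        f = r.lognormal(p.de_loc, p.de_scale, 3)
        f[f < 1] = 1 / f[f < 1]
        exp_fc[-1, ag] = f
        expected = base * exp_fc
        expected /= expected.sum(1, keepdims=True)
        np.testing.assert_allclose(programs, expected)
        np.testing.assert_allclose(fc, exp_fc)

    def test_all_de_factors_at_least_one(self):
        p = SimParams(n_cells=10, n_genes=5000, seed=5)
        _, fc = sample_programs(p, _rng(5))
        assert (fc >= 1).all()

    def test_programs_are_proportions(self):
        p = SimParams(n_cells=10, n_genes=2000, activity_n_genes=100, seed=2)
        programs, _ = sample_programs(p, _rng(2))
        assert (programs > 0).all()
        np.testing.assert_allclose(programs.sum(axis=1), 1.0)

    def test_too_many_activity_genes_rejected(self):
        p = SimParams(n_genes=100, activity_n_genes=200)
        with pytest.raises(ValueError, match="activity_n_genes"):
            sample_programs(p, _rng(0))


class TestAssignCells:
    def test_zero_activity_fraction(self):
        p = SimParams(n_cells=500, n_genes=100, activity_n_genes=10,
                      activity_frac=0.0, seed=1)
        _, phi, _ = assign_cells(p, _rng(1))
        assert (phi == 0).all()

    def test_expected_activity_cell_count(self):
        p = SimParams(n_cells=15_000, n_genes=100, activity_n_genes=10, seed=4)
        identity, phi, act_types = assign_cells(p, _rng(4))
        # ~1154 cells per type, ~1385 activity cells in expectation
        n_act = (phi > 0).sum()
        expect = 0.30 * 4 * 15_000 / 13
        sd = np.sqrt(expect)  # binomial-scale fluctuation
        assert abs(n_act - expect) < 4 * sd
        assert set(identity[phi > 0]) <= set(act_types)
        assert ((phi == 0) | ((phi >= 0.1) & (phi <= 0.7))).all()

    def test_skewed_celltype_probs(self):
        probs = (0.215, 0.210, 0.195, 0.130, 0.0924, 0.0328, 0.028, 0.0269,
                 0.0149, 0.0119, 0.0114, 0.009, 0.009, 0.008, 0.006)
        p = SimParams(n_cells=20_000, n_genes=100, activity_n_genes=10,
                      n_identity=len(probs), celltype_probs=probs, seed=6)
        identity, _, _ = assign_cells(p, _rng(6))
        freq = np.bincount(identity, minlength=len(probs)) / 20_000
        for f, q in zip(freq, probs):
            assert abs(f - q) < 4 * np.sqrt(q * (1 - q) / 20_000) + 1e-9


class TestSimulateCounts:
    def test_counts_are_nonnegative_integers(self):
        p = SimParams(n_cells=50, n_genes=300, activity_n_genes=30, seed=8)
        programs, _ = sample_programs(p, _rng(8))
        identity, phi, _ = assign_cells(p, _rng(8))
        counts, _ = simulate_counts(programs, identity, phi, p, _rng(8))
        assert counts.dtype.kind == "i"
        assert (counts >= 0).all()

    def test_overdispersion_follows_the_bcv_trend(self):
        # with fixed library size the Fano factor of a gene with mean count
        # m is 1 + (b + 1/sqrt(m))^2 * m (the gamma-Poisson mixture with the
        # mean-dependent trend); as the common dispersion b vanishes the
        # high-count Fano tends to 2, not 1, because the trend term remains
        p = SimParams(n_cells=4000, n_genes=20, activity_n_genes=2,
                      activity_frac=0.0, activity_celltypes=2,
                      bcv_dispersion=1e-4, bcv_dof=1e6,
                      lib_scale=1e-9, lib_loc=np.log(2000.0), de_prob=0.0,
                      expout_prob=0.0, seed=9)
        programs, _ = sample_programs(p, _rng(9))
        identity, phi, _ = assign_cells(p, _rng(9))
        counts, _ = simulate_counts(programs, identity, phi, p, _rng(9))
        j = programs[0].argmax()
        m = 2000.0 * programs[0, j]
        expected = 1.0 + (p.bcv_dispersion + 1 / np.sqrt(m)) ** 2 * m
        ratio = counts[:, j].var(ddof=1) / counts[:, j].mean()
        assert ratio == pytest.approx(expected, rel=0.15)
        assert expected == pytest.approx(2.0, rel=0.05)

    def test_mixing_equation_in_expectation(self):
        # phi=0.5 with two programs differing in one gene: that gene's mean
        # sits at the arithmetic midpoint scaled by the library size
        p = SimParams(n_cells=6000, n_genes=10, n_identity=2,
                      activity_n_genes=1, bcv_dispersion=1e-4, bcv_dof=1e6,
                      lib_scale=1e-9, lib_loc=np.log(1000.0), seed=12)
        programs = np.tile(np.full(10, 0.1), (3, 1))
        programs[2, 0], programs[2, 1] = 0.18, 0.02  # activity differs
        identity = np.zeros(6000, dtype=int)
        phi = np.full(6000, 0.5)
        counts, _ = simulate_counts(programs, identity, phi, p, _rng(12))
        mean0 = counts[:, 0].mean()
        expected = 1000.0 * (0.5 * 0.18 + 0.5 * 0.1)
        assert abs(mean0 - expected) / expected < 0.05


class TestDoublets:
    def _toy_truth(self, counts):
        n = counts.shape[0]
        return SimTruth(
            identity=np.zeros(n, dtype=int), phi=np.zeros(n),
            library_size=counts.sum(1).astype(float),
            is_doublet=np.zeros(n, dtype=bool),
            doublet_parents=np.full((n, 2), -1),
            programs=np.ones((2, counts.shape[1])) / counts.shape[1],
            de_foldchange=np.ones((2, counts.shape[1])),
            activity_celltypes=np.array([0]), n_singlets=n,
        )

    def test_doublet_total_equals_max_parent_total(self):
        rng = _rng(0)
        counts = rng.poisson(5.0, size=(40, 30))
        truth = self._toy_truth(counts)
        out, t2 = make_doublets(counts, truth, 0.2, _rng(1))
        n_dbl = int(t2.is_doublet.sum())
        assert n_dbl == round(0.2 / 0.8 * 40)
        for i in np.flatnonzero(t2.is_doublet):
            a, b = t2.doublet_parents[i]
            assert out[i].sum() == max(counts[a].sum(), counts[b].sum())
            assert (out[i] <= counts[a] + counts[b]).all()

    def test_downsampling_expectation_and_zeros(self):
        vec = np.array([10, 0, 30])
        draws = np.array([downsample_counts(vec, 20, _rng(s))
                          for s in range(2000)])
        assert (draws[:, 1] == 0).all()          # zero stays zero
        assert (draws.sum(axis=1) == 20).all()
        np.testing.assert_allclose(draws.mean(axis=0), [5, 0, 15], atol=0.3)

    def test_zero_rate_is_identity(self):
        counts = _rng(0).poisson(5.0, size=(10, 5))
        truth = self._toy_truth(counts)
        out, t2 = make_doublets(counts, truth, 0.0, _rng(1))
        np.testing.assert_array_equal(out, counts)
        assert t2 is truth


class TestEndToEnd:
    def test_seed_reproducibility(self):
        p = SimParams(n_cells=100, n_genes=300, activity_n_genes=30, seed=21)
        c1, t1 = simulate(p)
        c2, t2 = simulate(p)
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())
        np.testing.assert_array_equal(t1.phi, t2.phi)

    def test_phi_values_respect_the_usage_bounds(self):
        p = SimParams(n_cells=300, n_genes=400, activity_n_genes=50,
                      doublet_rate=0.2, seed=31)
        _, truth = simulate(p)
        phi = truth.phi
        assert ((phi == 0) | ((phi >= 0.1) & (phi <= 0.7))).all()
        assert (phi[truth.is_doublet] == 0).all()

    def test_pure_identity_simulator_when_disabled(self, ):
        # activity_frac=0 and doublet_rate=0: plain identity-program model
        p = SimParams(n_cells=150, n_genes=400, activity_n_genes=40,
                      activity_frac=0.0, doublet_rate=0.0, seed=22)
        counts, truth = simulate(p)
        assert (truth.phi == 0).all()
        assert not truth.is_doublet.any()
        assert counts.shape == (150, 400)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimParams(doublet_rate=1.5).validate()
        with pytest.raises(ValueError):
            SimParams(activity_celltypes=20).validate()
        with pytest.raises(ValueError):
            SimParams(celltype_probs=(0.5, 0.4)).validate()
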