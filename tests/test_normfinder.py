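"""Unit tests for the intra/inter-group variance-decomposition ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import refstab as r

from conftest import random_positive_matrix
from oracles import literal_stability_oracle


def two_group_design(n_a, n_b):
    labels = {f"s{j}": ("a" if j < n_a else "b") for j in range(n_a + n_b)}
    return r.GroupDesign(labels), [f"s{j}" for j in range(n_a + n_b)]


class TestRemoveSampleEffect:
    def test_coregulated_genes_give_zero(self):
        col = np.array([1.0, 5.0, -2.0, 0.5])
        y = pd.DataFrame([col, col, col], index=list("abc"))
        assert np.allclose(r.remove_sample_effect(y).to_numpy(), 0.0)

    def test_sample_shift_absorbed(self, rng):
        y = pd.DataFrame(rng.normal(0, 1, (5, 8)))
        shifted = y.copy()
        shifted[3] = shifted[3] + 7.5  # constant added to one sample column
        z, z_shift = r.remove_sample_effect(y), r.remove_sample_effect(shifted)
        np.testing.assert_allclose(z.to_numpy(), z_shift.to_numpy(), atol=1e-12)

    def test_column_sums_zero(self, rng):
        y = pd.DataFrame(rng.normal(0, 2, (5, 12)))
        z = r.remove_sample_effect(y)
        np.testing.assert_allclose(z.sum(axis=0).to_numpy(), 0.0, atol=1e-12)


class TestGroupStatistics:
    def test_no_group_effect(self):
        design, samples = two_group_design(3, 3)
        rng = np.random.default_rng(0)
        half = rng.normal(0, 1, (4, 3))
        y = pd.DataFrame(np.hstack([half, half]), columns=samples)
        d, _, gamma2 = r.group_statistics(r.remove_sample_effect(y), design)
        np.testing.assert_allclose(d.to_numpy(), 0.0, atol=1e-12)
        assert gamma2 == 0.0

    def test_single_shifted_gene_zero_noise(self):
        # 3 genes, 2 groups of 3, zero noise; gene a shifted +1 in group b
        design, samples = two_group_design(3, 3)
        y = pd.DataFrame(0.0, index=list("abc"), columns=samples)
        y.loc["a", ["s3", "s4", "s5"]] = 1.0
        z = r.remove_sample_effect(y)
        # centering turns the +1 shift into +2/3 for a and -1/3 for b, c
        assert np.allclose(z.loc["a", ["s3", "s4", "s5"]], 2 / 3)
        assert np.allclose(z.loc["b", ["s3", "s4", "s5"]], -1 / 3)
        d, sigma2, _ = r.group_statistics(z, design)
        # equal group sizes: the group difference splits evenly
        assert d.loc["a", "b"] - d.loc["a", "a"] == pytest.approx(2 / 3)
        assert d.loc["b", "b"] - d.loc["b", "a"] == pytest.approx(-1 / 3)
        np.testing.assert_allclose(sigma2.to_numpy(), 0.0, atol=1e-12)

    def test_group_d_sums_to_zero_across_genes(self, rng):
        design, samples = two_group_design(5, 7)
        y = pd.DataFrame(rng.normal(0, 1, (6, 12)), columns=samples)
        d, _, _ = r.group_statistics(r.remove_sample_effect(y), design)
        np.testing.assert_allclose(d.sum(axis=0).to_numpy(), 0.0, atol=1e-10)


class TestStabilityValues:
    def test_ideal_gene_has_zero_rho(self):
        # perfectly co-regulated panel: z == 0, every rho == 0
        design, samples = two_group_design(3, 3)
        col = np.linspace(-1, 1, 6)
        y = pd.DataFrame(
            [col + 1.0, col - 0.5, col], index=list("abc"), columns=samples
        )
        res = r.stability_values(y, design)
        np.testing.assert_allclose(res.rho.to_numpy(), 0.0, atol=1e-12)

    def test_matches_literal_formula_oracle(self, rng):
        design, samples = two_group_design(3, 3)
        y = pd.DataFrame(
            rng.normal(0, 1, (4, 6)), index=list("abcd"), columns=samples
        )
        y.loc["a", ["s3", "s4", "s5"]] += 1.5
        res = r.stability_values(y, design)
        d, s2, gamma2, rho = literal_stability_oracle(y, design)
        assert res.gamma2 == pytest.approx(gamma2, rel=1e-9)
        for i in y.index:
            assert res.rho[i] == pytest.approx(rho[i], rel=1e-9)
            for g in ("a", "b"):
                assert res.d_raw.loc[i, g] == pytest.approx(d[(i, g)], abs=1e-12)
                assert res.sigma2.loc[i, g] == pytest.approx(s2[(i, g)], abs=1e-12)

    def test_parameter_recovery_spearman(self):
        # zero-mean group shifts (centering makes only relative shifts
        # identifiable) with intra-group SDs; truth = |shift|/2 + SD/sqrt(n)
        shifts = np.array([-2.0, -1.2, -0.6, -0.2, 0.2, 0.6, 1.2, 2.0])
        isds = np.array([0.5, 0.4, 0.3, 0.2, 0.25, 0.35, 0.45, 0.55])
        true_score = np.abs(shifts) / 2 + isds / np.sqrt(15)
        genes = [f"g{i}" for i in range(8)]
        design, samples = two_group_design(15, 15)
        correlations = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = np.zeros((8, 30))
            y[:, 15:] += shifts[:, None]
            y += rng.normal(0, isds[:, None], (8, 30))
            res = r.stability_values(
                pd.DataFrame(y, index=genes, columns=samples), design
            )
            correlations.append(
                spearmanr(res.rho[genes].to_numpy(), true_score).statistic
            )
        assert np.mean(correlations) >= 0.9

    def test_ungrouped_mode_ranks_by_z_variance(self, rng):
        y = np.log2(random_positive_matrix(rng, 5, 10))
        design = r.GroupDesign({c: "all" for c in y.columns})
        res = r.stability_values(y, design)
        assert res.ungrouped
        z_var = r.remove_sample_effect(y).var(axis=1, ddof=1)
        assert res.ranking == list(z_var.sort_values(kind="stable").index)

    def test_rank_distribution_uniform_under_null(self):
        # equally-stable genes should occupy every rank equally often
        genes = [f"g{i}" for i in range(6)]
        design, samples = two_group_design(5, 5)
        positions = {g: [] for g in genes}
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            y = pd.DataFrame(
                rng.normal(0, 0.5, (6, 10)), index=genes, columns=samples
            )
            res = r.stability_values(y, design)
            for pos, g in enumerate(res.ranking):
                positions[g].append(pos)
        mean_rank = {g: np.mean(p) for g, p in positions.items()}
        for g in genes:  # expected 2.5; SD of the mean ~ 0.12
            assert abs(mean_rank[g] - 2.5) < 0.5


class TestBestPair:
    def test_duplicate_stable_genes_win(self, rng):
        design, samples = two_group_design(4, 4)
        stable = np.concatenate([np.zeros(4), np.zeros(4)])
        y = pd.DataFrame(
            {
                "dup1": stable,
                "dup2": stable,
                "noisy1": rng.normal(0, 2, 8),
                "noisy2": np.concatenate([np.zeros(4), np.full(4, 3.0)]),
            },
            index=samples,
        ).T
        gene_i, gene_k, _ = r.best_pair(y + rng.normal(0, 0.01, y.shape), design)
        assert {gene_i, gene_k} == {"dup1", "dup2"}

    def test_exhaustive_search_equivalence(self, rng):
        design, samples = two_group_design(4, 5)
        y = pd.DataFrame(
            rng.normal(0, 1, (7, 9)),
            index=[f"g{i}" for i in range(7)],
            columns=samples,
        )
        res = r.stability_values(y, design)
        # oracle: brute-force pair scores from the literal pair formulas
        d, s2, gamma2, _ = literal_stability_oracle(y, design)
        n = {"a": 4, "b": 5}
        best_score, best = None, None
        for i, k in itertools.combinations(list(y.index), 2):
            acc = 0.0
            for g in ("a", "b"):
                d_pair = (d[(i, g)] + d[(k, g)]) / 2
                s2_pair = (s2[(i, g)] + s2[(k, g)]) / 4
                shrink = (
                    gamma2 / (gamma2 + s2_pair / n[g]) if gamma2 > 0 else 0.0
                )
                acc += abs(d_pair * shrink) + (s2_pair / n[g]) ** 0.5
            score = acc / 2
            if best_score is None or score < best_score:
                best_score, best = score, (i, k)
        assert set(res.best_pair) == set(best)
        assert res.best_pair_rho == pytest.approx(best_score, rel=1e-9)

    def test_opposite_shifts_cancel_in_pair(self):
        # mirrored group shifts: the pair's averaged d vanishes, beating
        # the best single gene
        design, samples = two_group_design(6, 6)
        rng = np.random.default_rng(42)
        y = pd.DataFrame(0.0, index=["up", "down", "flat"], columns=samples)
        y.loc["up", samples[6:]] = 1.0
        y.loc["down", samples[6:]] = -1.0
        y += rng.normal(0, 0.05, y.shape)
        res = r.stability_values(y, design)
        assert set(res.best_pair) == {"up", "down"}
        assert res.best_pair_rho <= res.rho.min()


class TestInvariances:
    def test_per_gene_rescaling_leaves_rho_invariant(self, rng):
        design, samples = two_group_design(5, 5)
        y = pd.DataFrame(
            rng.normal(0, 1, (5, 10)),
            index=[f"g{i}" for i in range(5)],
            columns=samples,
        )
        shifted = y.add(pd.Series(rng.uniform(-3, 3, 5), index=y.index), axis=0)
        rho_a = r.stability_values(y, design).rho
        rho_b = r.stability_values(shifted, design).rho
        np.testing.assert_allclose(rho_a.to_numpy(), rho_b.to_numpy(), atol=1e-10)
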