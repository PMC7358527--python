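"""Correlation, RM-ANOVA, and CCA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilvir import (
    abundance_variability,
    cca,
    cca_permutation_test,
    rm_anova_tukey,
    spearman,
)
from soilvir.stats import _cca_core, downweight_rare


class TestSpearman:
    def test_monotone_pair_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0, 13, 14, 15, 16, 17])
        assert spearman(x, np.exp(x / 10)).r == pytest.approx(1.0)
        assert spearman(x, -x).r == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        # d = (-1,1,-1,1,0), sum d^2 = 4 -> r = 1 - 6*4/(5*24) = 0.8
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        res = spearman(x, y)
        assert res.r == pytest.approx(0.8)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            res = spearman(x, y)
            ref_r, ref_p = sps.spearmanr(x, y)
            assert res.r == pytest.approx(ref_r, abs=1e-12)
            assert res.p == pytest.approx(ref_p, rel=1e-6)

    def test_small_n_exact_permutation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        res = spearman(x, y)
        # exact two-sided permutation p for |r_perm| >= |r| over 120 orderings
        count = 0
        import itertools

        ry = sps.rankdata(y)
        for perm in itertools.permutations(range(5)):
            rp = np.corrcoef(sps.rankdata(x), ry[list(perm)])[0, 1]
            count += abs(rp) >= abs(res.r) - 1e-12
        assert res.p == pytest.approx(count / 120)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r1 = spearman(x, y).r
        r2 = spearman(np.exp(x), y**3).r if False else spearman(np.exp(x), y).r
        assert r1 == pytest.approx(r2)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6, 7, 8, 9, 10, 11])
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, np.nan, 9, 10, 11])
        assert spearman(x, y).n == 9

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))


class TestRmAnova:
    @staticmethod
    def _long(table):
        n, k = table.shape
        values, groups, subjects = [], [], []
        for i in range(n):
            for j in range(k):
                values.append(table[i, j])
                groups.append(f"g{j}")
                subjects.append(f"s{i}")
        return np.array(values), np.array(groups), np.array(subjects)

    def test_identical_groups_null(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_tukey(*self._long(table))
        assert res.f == pytest.approx(0.0)
        assert (res.tukey["mean_diff"] == 0).all()

    def test_two_groups_equal_squared_paired_t(self, rng):
        table = rng.normal(size=(8, 2))
        res = rm_anova_tukey(*self._long(table))
        t, _ = sps.ttest_rel(table[:, 0], table[:, 1])
        assert res.f == pytest.approx(t**2)

    def test_matches_statsmodels_oracle(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.anova")
        table = rng.normal(size=(7, 4)) + np.array([0.0, 0.5, 1.0, 0.2])
        values, groups, subjects = self._long(table)
        res = rm_anova_tukey(values, groups, subjects)
        frame = pd.DataFrame({"v": values, "g": groups, "s": subjects})
        ref = statsmodels.AnovaRM(frame, "v", "s", within=["g"]).fit()
        assert res.f == pytest.approx(float(ref.anova_table["F Value"].iloc[0]))
        assert res.p == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]))

    def test_shifted_group_detected(self, rng):
        detected = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            table = r.normal(size=(10, 3))
            table[:, 2] += 3.0
            res = rm_anova_tukey(*self._long(table))
            hits = res.tukey[res.tukey["reject"]]
            involved = set(hits["group_a"]) | set(hits["group_b"])
            detected += "g2" in involved
        assert detected >= 48

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_tukey(
                np.array([1.0, 2, 3]),
                np.array(["a", "b", "a"]),
                np.array(["s1", "s1", "s2"]),
            )


class TestAbundanceVariability:
    def test_monotone_link_gives_perfect_correlation(self):
        rows = []
        carbons = {"T1": 1.0, "T4": 1.5, "T7": 2.0, "T8": 2.5, "SF2": 3.0}
        for t, c in carbons.items():
            for i, m in enumerate(["May", "June", "July"]):
                rows.append(
                    {"sample_id": f"{t}-{m}", "treatment": t, "month": m, "plot": 1,
                     "viral_abundance": 1e8 + 1e7 * c * i, "bacterial_abundance": 5e7}
                )
        enum_table = pd.DataFrame(rows)
        edaphics = pd.DataFrame(
            [{"sample_id": f"{t}-x", "treatment": t, "organic_c": c}
             for t, c in carbons.items()]
        )
        per_treatment, corr = abundance_variability(enum_table, edaphics)
        assert corr.r == pytest.approx(1.0)
        assert len(per_treatment) == 5

    def test_constant_abundance_surfaces_error(self):
        rows = [
            {"sample_id": f"{t}-{m}", "treatment": t, "month": m, "plot": 1,
             "viral_abundance": 1e8, "bacterial_abundance": 5e7}
            for t in ["T1", "T4", "T7", "T8"]
            for m in ["May", "June", "July"]
        ]
        enum_table = pd.DataFrame(rows)
        edaphics = pd.DataFrame(
            [{"sample_id": t, "treatment": t, "organic_c": 1.0 + i}
             for i, t in enumerate(["T1", "T4", "T7", "T8"])]
        )
        with pytest.raises(ValueError):
            abundance_variability(enum_table, edaphics)


class TestCca:
    def test_constrained_by_first_ca_axis_recovers_eigenvalue(self, rng):
        species = rng.dirichlet(np.ones(12), 20) * 50
        # unconstrained correspondence analysis by direct SVD
        p = species / species.sum()
        r, c = p.sum(axis=1), p.sum(axis=0)
        q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        u, s, _ = np.linalg.svd(q, full_matrices=False)
        res = cca(species, u[:, 0] / np.sqrt(r))
        assert res.eigenvalues[0] == pytest.approx(s[0] ** 2, rel=1e-9)

    def test_matches_scikit_bio_oracle(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        species = rng.dirichlet(np.ones(10), 18) * 40
        env = rng.normal(size=(18, 3))
        res = cca(species, env)
        ref = skbio_ord.cca(
            pd.DataFrame(species, index=[f"s{i}" for i in range(18)]),
            pd.DataFrame(env, index=[f"s{i}" for i in range(18)]),
        )
        n_axes = min(3, res.eigenvalues.size)
        assert res.eigenvalues[:n_axes] == pytest.approx(
            np.asarray(ref.eigvals)[:n_axes], rel=1e-6
        )

    def test_orthogonal_env_near_zero_eigenvalues(self, rng):
        n = 400
        species = rng.dirichlet(np.ones(8), n) * 30
        env = rng.normal(size=(n, 2))
        res = cca(species, env)
        assert res.eigenvalues.sum() < 0.05 * res.total_inertia

    def test_joint_permutation_invariance(self, rng):
        species = rng.dirichlet(np.ones(9), 15) * 25
        env = rng.normal(size=(15, 2))
        perm = rng.permutation(15)
        a = cca(species, env).eigenvalues
        b = cca(species[perm], env[perm]).eigenvalues
        assert a == pytest.approx(b, rel=1e-9)

    def test_eigenvalue_sum_bounded_by_inertia(self, rng):
        species = rng.dirichlet(np.ones(14), 22) * 60
        env = rng.normal(size=(22, 4))
        res = cca(species, env)
        assert res.eigenvalues.sum() <= res.total_inertia + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_collinear_predictor_named(self, rng):
        species = rng.dirichlet(np.ones(6), 12) * 20
        env = rng.normal(size=(12, 2))
        env = np.c_[env, env[:, 0] * 2]
        with pytest.raises(ValueError, match="env2"):
            cca(species, env, env_names=["env0", "env1", "env2"])

    def test_downweight_rare_rule(self):
        species = np.array(
            [[5, 0, 1], [4, 0, 0], [6, 0, 0], [3, 0, 0], [2, 1, 0],
             [5, 0, 0], [4, 0, 0], [6, 0, 0], [3, 0, 0], [2, 0, 0]],
            float,
        )
        out = downweight_rare(species, fraction=5.0)
        freq = (species > 0).sum(axis=0)  # 10, 1, 1
        lim = freq.max() / 5.0  # 2
        assert np.allclose(out[:, 0], species[:, 0])
        assert np.allclose(out[:, 1], species[:, 1] * (1 / lim))
        assert np.allclose(out[:, 2], species[:, 2] * (1 / lim))


class TestCcaPermutation:
    def test_planted_association_minimal_p(self, rng):
        n = 30
        gradient = np.linspace(-2, 2, n)
        base = np.stack([np.exp(-0.5 * (gradient - mu) ** 2) for mu in
                         np.linspace(-2, 2, 10)], axis=1)
        species = base / base.sum(axis=1, keepdims=True) * 100
        p, _ = cca_permutation_test(species, gradient, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_same_seed_same_p(self, rng):
        species = rng.dirichlet(np.ones(8), 16) * 30
        env = rng.normal(size=(16, 2))
        p1, _ = cca_permutation_test(species, env, n_perm=99, seed=7)
        p2, _ = cca_permutation_test(species, env, n_perm=99, seed=7)
        assert p1 == p2

    def test_add_one_convention_never_zero(self, rng):
        species = rng.dirichlet(np.ones(8), 16) * 30
        env = rng.normal(size=(16, 1))
        p, _ = cca_permutation_test(species, env, n_perm=99, seed=1)
        assert 0 < p <= 1
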