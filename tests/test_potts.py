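"""Potts model: reweighting, pseudolikelihood fit, effects, validation."""

import numpy as np
import pytest

from clefam import aa, potts
from clefam.potts import MutationalLandscape, PottsModel


def random_msa(n, L, seed, alphabet=aa.ALPHABET):
    rng = np.random.default_rng(seed)
    return ["".join(alphabet[i] for i in rng.integers(0, len(alphabet), L))
            for _ in range(n)]


class TestSequenceWeights:
    def test_identical_sequences(self):
        w = potts.sequence_weights(["RTVPSGPDPLHH"] * 5)
        assert np.allclose(w, 0.2)
        assert w.sum() == pytest.approx(1.0)

    def test_all_distant_sequences(self):
        msa = ["A" * 12, "C" * 12, "D" * 12]
        w = potts.sequence_weights(msa)
        assert np.allclose(w, 1.0)

    def test_hand_enumerated_neighbor_counts(self):
        # identities: s0~s1 = 1.0, s0~s2 = 0.8, s1~s2 = 0.8, s3 alone
        msa = ["AAAAA", "AAAAA", "AAAAC", "WWWWW"]
        w = potts.sequence_weights(msa, theta=0.8)
        assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3, 1.0])

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            potts.sequence_weights(["AA", "AAA"])


class TestFit:
    def test_independent_site_model(self):
        rng = np.random.default_rng(0)
        L, n = 6, 600
        probs = rng.dirichlet(np.ones(20) * 2, size=L)
        msa = ["".join(aa.ALPHABET[rng.choice(20, p=probs[i])] for i in range(L))
               for _ in range(n)]
        model = potts.fit_potts(msa, weights=np.ones(n))

        # field softmax reproduces empirical frequencies within shrinkage
        X = np.array([aa.encode(s) for s in msa])
        emp = np.array([np.bincount(X[:, i], minlength=20) / n for i in range(L)])
        pred = np.exp(model.h) / np.exp(model.h).sum(axis=1, keepdims=True)
        assert np.abs(pred - emp).max() < 0.05

        # coupling norms indistinguishable from a column-permuted null fit
        perm_msa = ["".join(cols) for cols in zip(*[
            [msa[k][i] for k in rng.permutation(n)] for i in range(L)])]
        null = potts.fit_potts(perm_msa, weights=np.ones(n))

        def norms(m):
            return np.array([np.linalg.norm(potts.zero_sum_gauge_block(m.J[i, j]))
                             for i in range(L) for j in range(L) if i != j])

        nf, nn = norms(model).mean(), norms(null).mean()
        assert abs(nf - nn) / nn < 0.25

    def test_duplicating_sequences_is_invariant(self):
        msa = random_msa(40, 4, seed=1)
        m1 = potts.fit_potts(msa)
        m2 = potts.fit_potts(msa * 2)
        assert np.allclose(m1.h, m2.h, atol=1e-4)
        assert np.allclose(m1.J, m2.J, atol=1e-4)
        assert m2.n_eff == pytest.approx(m1.n_eff)

    def test_gradient_matches_finite_differences(self):
        msa = random_msa(12, 3, seed=2, alphabet="ACDE")
        L, A = 3, 4
        w = np.ones(12)
        rng = np.random.default_rng(3)
        params = rng.normal(0, 0.1, L * A + (L * A) ** 2)
        f0, g = potts.pseudolikelihood_value_and_grad(params, msa, w, L, A,
                                                      0.01 * A, 0.01 * A * (L - 1))
        eps = 1e-6
        idx = rng.choice(len(params), size=40, replace=False)
        for i in idx:
            dp = np.zeros_like(params)
            dp[i] = eps
            fp, _ = potts.pseudolikelihood_value_and_grad(params + dp, msa, w, L, A,
                                                          0.01 * A, 0.01 * A * (L - 1))
            fm, _ = potts.pseudolikelihood_value_and_grad(params - dp, msa, w, L, A,
                                                          0.01 * A, 0.01 * A * (L - 1))
            fd = (fp - fm) / (2 * eps)
            assert fd == pytest.approx(g[i], rel=1e-5, abs=1e-7)

    def test_model_invariants(self):
        msa = random_msa(60, 4, seed=4)
        model = potts.fit_potts(msa)
        model.check_shapes()
        assert model.n_eff <= len(msa)

    def test_fit_errors(self):
        with pytest.raises(ValueError):
            potts.fit_potts(["A", "C"])          # L < 2
        with pytest.raises(ValueError):
            potts.fit_potts(["AA", "CC"], weights=np.zeros(2))


class TestEnergy:
    def test_zero_model(self):
        model = PottsModel.zeros(4)
        assert potts.energy(model, "ACDE") == 0.0

    def test_single_field(self):
        model = PottsModel.zeros(3)
        model.h[0, aa.AA_INDEX["A"]] = 2.5
        assert potts.energy(model, "ACD") == 2.5
        assert potts.energy(model, "CCD") == 0.0

    def test_matches_einsum_oracle(self):
        rng = np.random.default_rng(5)
        L = 5
        model = PottsModel.zeros(L)
        model.h = rng.normal(size=(L, 20))
        J = rng.normal(size=(L, L, 20, 20))
        J = 0.5 * (J + np.transpose(J, (1, 0, 3, 2)))
        for i in range(L):
            J[i, i] = 0.0
        model.J = J
        for s in random_msa(10, L, seed=6):
            x = aa.encode(s)
            oh = np.zeros((L, 20))
            oh[np.arange(L), x] = 1.0
            expected = float(np.einsum("ia,ia->", model.h, oh)
                             + 0.5 * np.einsum("ia,ijab,jb->", oh, model.J, oh))
            assert potts.energy(model, s) == pytest.approx(expected)

    def test_length_checked(self):
        with pytest.raises(ValueError):
            potts.energy(PottsModel.zeros(3), "ACDE")


class TestMutationalEffect:
    def random_model(self, L, seed):
        rng = np.random.default_rng(seed)
        model = PottsModel.zeros(L)
        model.h = rng.normal(size=(L, 20))
        J = rng.normal(scale=0.3, size=(L, L, 20, 20))
        J = 0.5 * (J + np.transpose(J, (1, 0, 3, 2)))
        for i in range(L):
            J[i, i] = 0.0
        model.J = J
        return model

    def test_wild_type_substitution_zero(self):
        model = self.random_model(4, 7)
        assert potts.mutational_effect(model, "ACDE", 2, "C") == 0.0

    def test_field_only_model_analytic(self):
        model = PottsModel.zeros(3)
        model.h = np.arange(60, dtype=float).reshape(3, 20)
        wt = "ACD"
        de = potts.mutational_effect(model, wt, 1, "W")
        assert de == model.h[0, aa.AA_INDEX["W"]] - model.h[0, aa.AA_INDEX["A"]]

    def test_incremental_equals_full_recompute(self):
        model = self.random_model(6, 8)
        rng = np.random.default_rng(9)
        wt = random_msa(1, 6, seed=10)[0]
        for _ in range(100):
            pos = int(rng.integers(1, 7))
            res = aa.ALPHABET[rng.integers(0, 20)]
            mut = wt[:pos - 1] + res + wt[pos:]
            assert potts.mutational_effect(model, wt, pos, res) == pytest.approx(
                potts.energy(model, mut) - potts.energy(model, wt), abs=1e-9)

    def test_position_bounds_one_based(self):
        model = self.random_model(4, 11)
        with pytest.raises(ValueError):
            potts.mutational_effect(model, "ACDE", 0, "W")
        with pytest.raises(ValueError):
            potts.mutational_effect(model, "ACDE", 5, "W")
        with pytest.raises(ValueError):
            potts.mutational_effect(model, "ACDE", 1, "X")


class TestLandscape:
    def test_zero_model_all_zero(self):
        land = potts.mutational_landscape(PottsModel.zeros(3), "ACD")
        assert np.all(land.effects == 0.0)

    def test_field_model_row_recentred(self):
        model = PottsModel.zeros(2)
        model.h = np.arange(40, dtype=float).reshape(2, 20)
        land = potts.mutational_landscape(model, "AC")
        i = 0
        a = aa.AA_INDEX["A"]
        expected = model.h[i] - model.h[i, a]
        expected[a] = 0.0
        assert np.allclose(land.effects[i], expected)

    def test_wild_type_cells_exactly_zero(self):
        model = TestMutationalEffect().random_model(5, 12)
        wt = random_msa(1, 5, seed=13)[0]
        land = potts.mutational_landscape(model, wt)
        x = aa.encode(wt)
        assert all(land.effects[i, x[i]] == 0.0 for i in range(5))

    def test_elementwise_consistency(self):
        model = TestMutationalEffect().random_model(4, 14)
        wt = "RTVP"
        land = potts.mutational_landscape(model, wt)
        for i in range(4):
            for b in range(20):
                assert land.effects[i, b] == pytest.approx(
                    potts.mutational_effect(model, wt, i + 1, aa.ALPHABET[b]))

    def test_gauge_shift_leaves_effects_unchanged(self):
        model = TestMutationalEffect().random_model(5, 15)
        wt = random_msa(1, 5, seed=16)[0]
        base = potts.mutational_landscape(model, wt).effects

        rng = np.random.default_rng(17)
        c = rng.normal(size=20)
        i = 2
        shifted = PottsModel(L=5, A=20, h=model.h.copy(), J=model.J.copy())
        shifted.h[i] += c
        for j in range(5):
            if j != i:
                shifted.J[i, j] -= c[:, None] / 4.0
                shifted.J[j, i] -= c[None, :] / 4.0
        shifted.check_shapes()
        assert np.allclose(potts.mutational_landscape(shifted, wt).effects,
                           base, atol=1e-9)


class TestCouplingMap:
    def test_zero_couplings_zero_map(self):
        assert np.all(potts.coupling_map(PottsModel.zeros(4)) == 0.0)

    def test_apc_annihilates_rank_one(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        F = np.outer(u, u)
        assert np.allclose(potts.apc(F), 0.0, atol=1e-10)

    def test_apc_zero_grand_mean(self):
        assert np.all(potts.apc(np.zeros((3, 3))) == 0.0)

    def test_symmetric_nonnegative_zero_diagonal(self):
        model = TestMutationalEffect().random_model(6, 18)
        cm = potts.coupling_map(model)
        assert np.allclose(cm, cm.T)
        assert np.all(cm >= 0.0)
        assert np.all(np.diag(cm) == 0.0)

    def test_zero_sum_gauge(self):
        rng = np.random.default_rng(19)
        g = potts.zero_sum_gauge_block(rng.normal(size=(20, 20)))
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-10)


class TestValidationRegressions:
    def planted_landscape(self, slope=0.5, intercept=1.0, wt="RTVPSGPDPLHH"):
        B = aa.blosum62()
        x = aa.encode(wt)
        effects = np.zeros((len(wt), 20))
        for i in range(len(wt)):
            for b in range(20):
                if b != x[i]:
                    effects[i, b] = slope * B[x[i], b] + intercept
        return MutationalLandscape(wt=wt, effects=effects)

    def test_planted_linearity_recovered(self):
        land = self.planted_landscape()
        resid, xs, rep = potts.residualize_blosum(land)
        assert rep.slope == pytest.approx(0.5)
        assert rep.intercept == pytest.approx(1.0)
        assert rep.r2 == pytest.approx(1.0)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_report_matches_normal_equations(self):
        rng = np.random.default_rng(20)
        land = self.planted_landscape()
        land.effects += rng.normal(0, 0.3, size=land.effects.shape)
        resid, xs, rep = potts.residualize_blosum(land)
        ys = []
        x = aa.encode(land.wt)
        for i in range(len(land.wt)):
            for b in range(20):
                if b != x[i]:
                    ys.append(land.effects[i, b])
        ys = np.array(ys)
        X = np.column_stack([xs, np.ones_like(xs)])
        beta = np.linalg.solve(X.T @ X, X.T @ ys)
        assert rep.slope == pytest.approx(beta[0])
        assert rep.intercept == pytest.approx(beta[1])
        pred = X @ beta
        assert rep.mse == pytest.approx(np.mean((ys - pred) ** 2))
        assert rep.r2 == pytest.approx(
            1 - np.sum((ys - pred) ** 2) / np.sum((ys - ys.mean()) ** 2))

    def test_sneath_planted_monotone(self):
        wt = "RTVPSGPDPLHH"
        table = aa.biochemical_dissimilarity()
        x = aa.encode(wt)
        resid = np.array([-2.0 * table[x[i], b]
                          for i in range(len(wt)) for b in range(20) if b != x[i]])
        rep = potts.sneath_correlation(resid, wt)
        assert rep.spearman == pytest.approx(-1.0)
        assert rep.r2 > 0.99

    def test_sneath_shuffled_uncorrelated(self):
        rng = np.random.default_rng(21)
        wt = "RTVPSGPDPLHH"
        resid = rng.normal(size=12 * 19)
        rep = potts.sneath_correlation(resid, wt)
        assert abs(rep.spearman) < 0.15

    def test_constant_predictor_rejected(self):
        wt = "RTVP"
        table = np.full((20, 20), 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            potts.sneath_correlation(np.zeros(4 * 19), wt, table=table)

    def test_sneath_table_validated(self):
        with pytest.raises(ValueError, match="20x20"):
            potts.sneath_correlation(np.zeros(19), "A", table=np.zeros((3, 3)))


class TestConservationScore:
    def test_arithmetic(self):
        assert potts.conservation_score([0.7, 0.5, 0.9]) == pytest.approx(2 / 3)
        assert potts.conservation_score([0.9, 0.8]) == 1.0
        assert potts.conservation_score([0.6]) == 0.0     # strict inequality

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            potts.conservation_score([])


class TestSerialization:
    def test_bit_exact_roundtrip(self, tmp_path):
        model = TestMutationalEffect().random_model(4, 22)
        model.lambda_h = 0.2
        model.lambda_J = 0.6
        model.n_eff = 37.5
        p = tmp_path / "model.json"
        model.to_json(p)
        back = PottsModel.from_json(p)
        assert np.array_equal(model.h, back.h)
        assert np.array_equal(model.J, back.J)
        assert (back.lambda_h, back.lambda_J, back.theta, back.n_eff) == \
            (0.2, 0.6, 0.8, 37.5)
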