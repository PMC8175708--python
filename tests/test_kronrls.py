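"""KronRLS solvers against dense vectorized-system oracles."""

import numpy as np
import pytest

from conftest import random_pd_kernel
from kronbind.io import InteractionTable
from kronbind.kernels import KernelMatrix
from kronbind.kronrls import (
    TrainSpec,
    fit_cg,
    fit_complete,
    fitted_values,
    load_model,
    loco_cv,
    predict,
    save_model,
)


def dense_complete_solve(Kc, Kp, Y, lam):
    """Oracle: solve the vectorized (Kp (x) Kc + lam I) system densely."""
    n = Y.size
    Kk = np.kron(Kp.values, Kc.values)
    a = np.linalg.solve(Kk + lam * np.eye(n), Y.reshape(-1, order="F"))
    A = a.reshape(Y.shape, order="F")
    return Kc.values @ A @ Kp.values


def dense_sampled_solve(Kc, Kp, table, lam):
    """Oracle: solve the sampled m x m system densely, return predictions
    on all kernel cells."""
    cidx, pidx = Kc.index(), Kp.index()
    pairs = table.pairs()
    rows = [cidx[c] for c, _ in pairs]
    cols = [pidx[p] for _, p in pairs]
    m = len(pairs)
    G = np.empty((m, m))
    for u in range(m):
        for v in range(m):
            G[u, v] = Kc.values[rows[u], rows[v]] * Kp.values[cols[u], cols[v]]
    a = np.linalg.solve(G + lam * np.eye(m), table.frame.pkd.to_numpy())
    A = np.zeros((Kc.n, Kp.n))
    for coeff, r, c in zip(a, rows, cols):
        A[r, c] += coeff
    return Kc.values @ A @ Kp.values


class TestFitComplete:
    def test_identity_kernels_reduce_to_ridge_shrinkage(self):
        n_c, n_p, lam = 4, 3, 0.5
        Kc = KernelMatrix(tuple(f"c{i}" for i in range(n_c)), np.eye(n_c))
        Kp = KernelMatrix(tuple(f"p{i}" for i in range(n_p)), np.eye(n_p))
        Y = np.random.default_rng(0).normal(size=(n_c, n_p))
        model = fit_complete(Kc, Kp, Y, TrainSpec(lam=lam))
        assert np.allclose(fitted_values(model), Y / (1 + lam))

    def test_small_lambda_interpolates_pd_kernels(self):
        Kc = random_pd_kernel(4, 1)
        Kp = random_pd_kernel(3, 2)
        Y = np.random.default_rng(3).normal(size=(4, 3))
        model = fit_complete(Kc, Kp, Y, TrainSpec(lam=1e-10))
        assert np.allclose(fitted_values(model), Y, atol=1e-5)

    @pytest.mark.parametrize("n_c,n_p,lam", [(2, 2, 1.0), (4, 3, 0.5), (5, 6, 2.0)])
    def test_matches_dense_kronecker_oracle(self, n_c, n_p, lam):
        Kc = random_pd_kernel(n_c, n_c)
        Kp = random_pd_kernel(n_p, 10 + n_p)
        Y = np.random.default_rng(n_c * n_p).normal(size=(n_c, n_p))
        model = fit_complete(Kc, Kp, Y, TrainSpec(lam=lam))
        assert np.allclose(
            fitted_values(model), dense_complete_solve(Kc, Kp, Y, lam), atol=1e-8
        )

    def test_dimension_mismatch_rejected(self):
        Kc, Kp = random_pd_kernel(3, 0), random_pd_kernel(3, 1)
        with pytest.raises(ValueError, match="shape"):
            fit_complete(Kc, Kp, np.zeros((2, 3)), TrainSpec())

    def test_training_rmse_nondecreasing_in_lambda(self):
        Kc, Kp = random_pd_kernel(5, 4), random_pd_kernel(4, 5)
        Y = np.random.default_rng(9).normal(size=(5, 4))
        rmses = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            model = fit_complete(Kc, Kp, Y, TrainSpec(lam=lam))
            rmses.append(float(np.sqrt(np.mean((fitted_values(model) - Y) ** 2))))
        assert rmses == sorted(rmses)


class TestFitCG:
    def _full_table(self, Kc, Kp, Y):
        return InteractionTable.from_rows(
            [
                (c, p, abs(float(Y[i, j])))
                for i, c in enumerate(Kc.ids)
                for j, p in enumerate(Kp.ids)
            ]
        )

    def test_agrees_with_fit_complete_on_full_labels(self):
        Kc, Kp = random_pd_kernel(4, 7), random_pd_kernel(3, 8)
        Y = np.abs(np.random.default_rng(5).normal(size=(4, 3)))
        table = self._full_table(Kc, Kp, Y)
        spec = TrainSpec(lam=0.8, epochs=5000, tol=1e-14)
        dense = fitted_values(fit_complete(Kc, Kp, Y, spec))
        sparse = fitted_values(fit_cg(Kc, Kp, table, spec))
        assert np.allclose(dense, sparse, atol=1e-6)

    def test_zero_epochs_gives_zero_model(self):
        Kc, Kp = random_pd_kernel(3, 0), random_pd_kernel(3, 1)
        table = InteractionTable.from_rows([("e0", "e1", 6.0)])
        model = fit_cg(Kc, Kp, table, TrainSpec(epochs=0))
        assert np.all(model.dual == 0)
        pairs = [("e0", "e0"), ("e2", "e1")]
        assert np.all(predict(model, pairs).values_for(pairs) == 0)

    def test_sparse_toy_matches_dense_sampled_oracle(self):
        Kc = random_pd_kernel(3, 21, ids=("a", "b", "c"))
        Kp = random_pd_kernel(3, 22, ids=("x", "y", "z"))
        table = InteractionTable.from_rows(
            [("a", "x", 6.0), ("a", "z", 7.5), ("b", "y", 5.0),
             ("c", "x", 8.0), ("c", "z", 4.5)]
        )
        spec = TrainSpec(lam=0.6, epochs=2000, tol=1e-14)
        mine = fitted_values(fit_cg(Kc, Kp, table, spec))
        oracle = dense_sampled_solve(Kc, Kp, table, 0.6)
        assert np.allclose(mine, oracle, atol=1e-8)

    def test_unknown_entity_raises_key_error(self):
        Kc, Kp = random_pd_kernel(2, 1), random_pd_kernel(2, 2)
        table = InteractionTable.from_rows([("nope", "e0", 6.0)])
        with pytest.raises(KeyError, match="nope"):
            fit_cg(Kc, Kp, table, TrainSpec())

    def test_deterministic(self):
        Kc, Kp = random_pd_kernel(4, 2), random_pd_kernel(4, 3)
        table = InteractionTable.from_rows(
            [("e0", "e1", 6.0), ("e2", "e3", 7.0), ("e1", "e0", 5.5)]
        )
        m1 = fit_cg(Kc, Kp, table, TrainSpec(lam=1.0, epochs=50))
        m2 = fit_cg(Kc, Kp, table, TrainSpec(lam=1.0, epochs=50))
        assert np.array_equal(m1.dual, m2.dual)


class TestPredict:
    def test_matches_brute_force_summation(self):
        Kc = random_pd_kernel(4, 31)
        Kp = random_pd_kernel(3, 32)
        table = InteractionTable.from_rows(
            [("e0", "e1", 6.0), ("e2", "e0", 7.0), ("e3", "e2", 5.5)]
        )
        model = fit_cg(Kc, Kp, table, TrainSpec(lam=0.9, epochs=500))
        cidx, pidx = Kc.index(), Kp.index()
        query = [(c, p) for c in Kc.ids for p in Kp.ids]
        pred = predict(model, query)
        for c, p in query:
            brute = sum(
                coeff * Kc.values[cidx[c], cidx[tc]] * Kp.values[pidx[p], pidx[tp]]
                for coeff, (tc, tp) in zip(model.dual, model.train_pairs)
            )
            assert pred.entries[(c, p)] == pytest.approx(brute, abs=1e-10)

    def test_duplicate_queries_identical(self):
        Kc, Kp = random_pd_kernel(3, 1), random_pd_kernel(3, 2)
        table = InteractionTable.from_rows([("e0", "e0", 6.0)])
        model = fit_cg(Kc, Kp, table, TrainSpec(epochs=100))
        pred = predict(model, [("e1", "e1"), ("e1", "e1")])
        vals = pred.values_for([("e1", "e1")])
        assert len(pred.entries) == 1 and np.isfinite(vals).all()

    def test_interpolating_model_recovers_training_labels(self):
        Kc, Kp = random_pd_kernel(4, 11), random_pd_kernel(4, 12)
        Y = np.abs(np.random.default_rng(13).normal(size=(4, 4))) + 4.0
        model = fit_complete(Kc, Kp, Y, TrainSpec(lam=1e-9))
        pairs = [(c, p) for c in Kc.ids for p in Kp.ids]
        pred = predict(model, pairs).values_for(pairs)
        assert np.allclose(pred, Y.reshape(-1), atol=1e-4)

    def test_invariant_to_simultaneous_permutation(self):
        rng = np.random.default_rng(17)
        Kc, Kp = random_pd_kernel(4, 41), random_pd_kernel(4, 42)
        table = InteractionTable.from_rows(
            [("e0", "e1", 6.0), ("e2", "e3", 7.0), ("e3", "e0", 5.0), ("e1", "e2", 8.0)]
        )
        spec = TrainSpec(lam=0.7, epochs=1000, tol=1e-13)
        base = predict(fit_cg(Kc, Kp, table, spec), table.pairs())
        perm = rng.permutation(4)
        Kc2 = KernelMatrix(
            tuple(np.array(Kc.ids)[perm]), Kc.values[np.ix_(perm, perm)]
        )
        shuffled_rows = table.frame.sample(frac=1.0, random_state=3)
        table2 = InteractionTable(shuffled_rows)
        alt = predict(fit_cg(Kc2, Kp, table2, spec), table.pairs())
        for pair in table.pairs():
            assert alt.entries[pair] == pytest.approx(base.entries[pair], abs=1e-7)


class TestLocoCV:
    def _dataset(self):
        Kc = random_pd_kernel(5, 51)
        Kp = random_pd_kernel(4, 52)
        rng = np.random.default_rng(53)
        rows = [
            (c, p, float(rng.uniform(4, 9)))
            for c in Kc.ids
            for p in Kp.ids
            if rng.random() < 0.8
        ]
        return Kc, Kp, InteractionTable.from_rows(rows)

    def test_single_spec_grid_selected_trivially(self):
        Kc, Kp, table = self._dataset()
        spec = TrainSpec(lam=1.0, epochs=200)
        result = loco_cv(Kc, Kp, table, [spec])
        assert all(s == spec for s in result.selected.values())

    def test_every_compound_held_out_exactly_once(self):
        Kc, Kp, table = self._dataset()
        result = loco_cv(Kc, Kp, table, [TrainSpec(lam=1.0, epochs=200)])
        assert sorted(result.fold_of) == table.compounds()
        assert len(set(result.fold_of.values())) == len(table.compounds())
        assert result.predictions.pairs() == set(table.pairs())

    def test_grid_selection_prefers_lower_rmse(self):
        Kc, Kp, table = self._dataset()
        grid = [TrainSpec(lam=0.1, epochs=500), TrainSpec(lam=50.0, epochs=500)]
        result = loco_cv(Kc, Kp, table, grid, inner_folds=2)
        # a huge lambda shrinks predictions toward 0, far from pKd ~4-9
        assert all(s.lam == 0.1 for s in result.selected.values())

    def test_requires_two_compounds(self):
        Kc, Kp = random_pd_kernel(2, 1), random_pd_kernel(2, 2)
        table = InteractionTable.from_rows([("e0", "e0", 6.0), ("e0", "e1", 7.0)])
        with pytest.raises(ValueError, match="2 distinct"):
            loco_cv(Kc, Kp, table, [TrainSpec()])


class TestSerialization:
    def test_sparse_model_round_trip(self, tmp_path):
        Kc, Kp = random_pd_kernel(3, 61), random_pd_kernel(3, 62)
        table = InteractionTable.from_rows([("e0", "e1", 6.0), ("e2", "e2", 7.5)])
        model = fit_cg(Kc, Kp, table, TrainSpec(lam=0.4, epochs=300))
        header = save_model(model, tmp_path, "m")
        back = load_model(header, Kc, Kp)
        pairs = [(c, p) for c in Kc.ids for p in Kp.ids]
        assert np.allclose(
            predict(model, pairs).values_for(pairs),
            predict(back, pairs).values_for(pairs),
        )

    def test_complete_model_round_trip(self, tmp_path):
        Kc, Kp = random_pd_kernel(3, 63), random_pd_kernel(2, 64)
        Y = np.abs(np.random.default_rng(65).normal(size=(3, 2)))
        model = fit_complete(Kc, Kp, Y, TrainSpec(lam=1.2))
        header = save_model(model, tmp_path, "mc")
        back = load_model(header, Kc, Kp)
        assert np.allclose(fitted_values(model), fitted_values(back))
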