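"""FROLS/ERR term selection against independent least-squares oracles."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from qsarx.frols import (
    CANONICAL_LABELS,
    CollinearityWarning,
    DesignMatrix,
    SelectedModel,
    build_design_matrix,
    descriptor_table,
    err_ratio,
    estimate_weights,
    frols_select,
    predict,
)
from qsarx.descriptors import CompoundRecord


def random_dictionary(seed, n=40, m=10):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    labels = CANONICAL_LABELS[:m]
    return X, labels


class TestErrRatio:
    def test_perfect_alignment(self):
        y = np.array([1.0, 2.0, -3.0])
        assert err_ratio(y, y) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert err_ratio(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_example(self):
        # (y.p)^2 / (p.p y.y) = 1 / (1*5)
        assert err_ratio(np.array([1.0, 2.0]), np.array([1.0, 0.0])) == pytest.approx(0.2)

    def test_zero_norm_signals(self):
        with pytest.raises(ZeroDivisionError):
            err_ratio(np.zeros(3), np.ones(3))

    @given(
        vecs=hnp.arrays(np.float64, (2, 6), elements=st.floats(-50, 50)),
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_positive_rescaling(self, vecs, a, b):
        y, p = vecs
        if np.linalg.norm(y) < 1e-6 or np.linalg.norm(p) < 1e-6:
            return
        base = err_ratio(y, p)
        assert 0.0 <= base <= 1.0 + 1e-12
        assert err_ratio(a * y, b * p) == pytest.approx(base, abs=1e-9)


class TestEstimateWeights:
    def test_identity_design(self):
        y = np.array([3.0, -1.0, 2.0])
        assert estimate_weights(np.eye(3), y) == pytest.approx(y)

    def test_single_column_scaling(self):
        z = np.array([1.0, 2.0, 3.0])
        beta = estimate_weights(z.reshape(-1, 1), 2 * z)
        assert beta == pytest.approx([2.0])

    def test_hand_normal_equations(self):
        Z = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        beta = estimate_weights(Z, np.array([1.0, 2.0, 3.0]))
        assert beta == pytest.approx([1.0, 1.0])

    def test_residual_orthogonal_to_columns(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        beta = estimate_weights(Z, y)
        assert Z.T @ (y - Z @ beta) == pytest.approx(np.zeros(4), abs=1e-9)

    def test_rank_deficiency_names_columns(self):
        Z = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(np.linalg.LinAlgError, match="column indices"):
            estimate_weights(Z, np.array([1.0, 2.0, 3.0]))


class TestDesignMatrix:
    def make_records(self, ie=(90.0, 80.0, 70.0)):
        return [
            CompoundRecord(name=f"c{i}", mw=200 + i, pka=3 + i, logp=1.0, logs=-3.0,
                           psa=50.0, alpha=30.0, e_homo=-5.5 + 0.1 * i, e_lumo=-3.0,
                           ie_obs=v)
            for i, v in enumerate(ie)
        ]

    def test_label_order_follows_request(self):
        D = build_design_matrix(self.make_records(), labels=["x2", "x7"])
        assert D.labels == ("pka", "e_homo")
        assert D.columns.shape == (3, 2)
        assert D.columns[:, 0] == pytest.approx([3.0, 4.0, 5.0])

    def test_missing_response_named_in_diagnostic(self):
        records = self.make_records()
        records.append(
            CompoundRecord(name="orphan", mw=100, pka=2, logp=0, logs=-2, psa=40,
                           alpha=20, e_homo=-5.0, e_lumo=-3.0)
        )
        with pytest.warns(UserWarning, match="orphan"):
            D = build_design_matrix(records, labels=["pka"])
        assert D.n_obs == 3
        with pytest.raises(ValueError, match="orphan"):
            build_design_matrix(records, labels=["pka"], strict=True)

    def test_reference_table_omega_column_passthrough(self, high_efficiency_table):
        # tabulated omega values are used verbatim as the x9 column
        table = high_efficiency_table.copy()
        D = build_design_matrix(table, labels=["pka", "e_homo", "e_lumo", "omega", "delta_n"])
        assert D.columns.shape == (10, 5)
        assert D.columns[:, 3] == pytest.approx(table["omega"].to_numpy())

    def test_zero_variance_column_warns_but_is_retained(self):
        records = self.make_records()
        with pytest.warns(UserWarning, match="zero-variance"):
            D = build_design_matrix(records, labels=["logp", "pka"])
        assert D.labels == ("logp", "pka")

    def test_opt_in_intercept_and_standardization(self):
        D = build_design_matrix(self.make_records(), labels=["pka", "e_homo"],
                                add_intercept=True, standardize=True)
        assert D.labels == ("intercept", "pka", "e_homo")
        assert D.column("intercept") == pytest.approx(np.ones(3))
        assert D.column("pka").mean() == pytest.approx(0.0, abs=1e-12)
        assert D.column("pka").std() == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            DesignMatrix(labels=("a",), columns=np.array([[np.inf], [1.0]]),
                         response=np.array([1.0, 2.0]))


class TestFrolsSelect:
    def test_exact_single_candidate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = X[:, 2].copy()
        D = DesignMatrix(labels=("a", "b", "c", "d"), columns=X, response=y)
        model = frols_select(D, rho=0.005)
        assert model.terms == (2,)
        assert model.err_per_term == pytest.approx([1.0])
        assert model.esr == pytest.approx(0.0, abs=1e-12)

    def test_two_term_noiseless_recovery_matches_exhaustive_subsets(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = 3.0 * X[:, 1] + 0.5 * X[:, 4]
        D = DesignMatrix(labels=tuple("abcdef"), columns=X, response=y)
        model = frols_select(D, rho=0.005)
        assert set(model.terms) == {1, 4}
        assert model.esr < 1e-10
        coef = model.coefficients()
        assert coef["b"] == pytest.approx(3.0, abs=1e-8)
        assert coef["e"] == pytest.approx(0.5, abs=1e-8)
        # oracle: exhaustive 2-subset least squares must agree on the winner
        best_rss, best_pair = np.inf, None
        for pair in itertools.combinations(range(6), 2):
            beta, *_ = np.linalg.lstsq(X[:, pair], y, rcond=None)
            rss = float(np.sum((y - X[:, pair] @ beta) ** 2))
            if rss < best_rss:
                best_rss, best_pair = rss, pair
        assert set(best_pair) == set(model.terms)

    def test_rho_zero_reproduces_full_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        D = DesignMatrix(labels=("a", "b", "c"), columns=X, response=y)
        model = frols_select(D, rho=0.0, min_gain=0.0)
        assert len(model.terms) == 3
        beta_full = np.linalg.lstsq(X, y, rcond=None)[0]
        for j, w in zip(model.terms, model.weights):
            assert w == pytest.approx(beta_full[j], abs=1e-8)

    def test_full_model_matches_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        D = DesignMatrix(labels=tuple("abcde"), columns=X, response=y)
        model = frols_select(D, rho=0.0, min_gain=0.0)
        ref = sklearn.LinearRegression(fit_intercept=False).fit(X, y).coef_
        for j, w in zip(model.terms, model.weights):
            assert w == pytest.approx(ref[j], abs=1e-8)

    def test_matches_exhaustive_best_subset_on_orthogonal_design(self):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        y = 2.0 * Q[:, 0] - 1.0 * Q[:, 3] + 0.05 * rng.normal(size=30)
        D = DesignMatrix(labels=tuple("abcde"), columns=Q, response=y)
        model = frols_select(D, rho=0.0, max_terms=2, min_gain=0.0)
        best_rss, best_pair = np.inf, None
        for pair in itertools.combinations(range(5), 2):
            beta, *_ = np.linalg.lstsq(Q[:, pair], y, rcond=None)
            rss = float(np.sum((y - Q[:, pair] @ beta) ** 2))
            if rss < best_rss:
                best_rss, best_pair = rss, pair
        assert set(model.terms) == set(best_pair)

    def test_err_sum_bounded_and_esr_nonincreasing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        D = DesignMatrix(labels=CANONICAL_LABELS[:8], columns=X, response=y)
        model = frols_select(D, rho=0.0, min_gain=0.0)
        assert np.all(model.err_per_term >= -1e-12)
        assert model.serr <= 1.0 + 1e-10
        esr_traj = 1.0 - np.cumsum(model.err_per_term)
        assert np.all(np.diff(esr_traj) <= 1e-12)

    def test_deterministic_and_lowest_index_tie_break(self):
        # two identical candidates: the lower index must win, deterministically
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), x, x])
        y = 2.0 * x
        with pytest.warns(UserWarning, match="zero-variance"):
            D = DesignMatrix(labels=("a", "b", "c"), columns=X, response=y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            m1 = frols_select(D, rho=0.0)
            m2 = frols_select(D, rho=0.0)
        assert m1.terms == m2.terms
        assert m1.terms[0] == 1

    def test_collinear_candidate_skipped_with_diagnostic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, 2 * x, np.array([1.0, -1.0, 1.0, -1.0])])
        y = x + np.array([0.1, -0.1, 0.1, -0.1])
        D = DesignMatrix(labels=("a", "b", "c"), columns=X, response=y)
        with pytest.warns(CollinearityWarning, match="'b'"):
            model = frols_select(D, rho=0.0, min_gain=0.0)
        assert 1 not in model.terms
        assert 1 in model.skipped_collinear

    def test_invalid_rho_rejected(self):
        D = DesignMatrix(labels=("a",), columns=np.arange(1.0, 4.0).reshape(-1, 1),
                         response=np.arange(3.0))
        with pytest.raises(ValueError, match="rho"):
            frols_select(D, rho=1.0)


class TestPredict:
    def publication_model(self):
        labels = CANONICAL_LABELS
        terms = tuple(labels.index(k) for k in ("e_homo", "delta_n", "e_lumo", "omega", "pka"))
        weights = np.array([812.1748, 33.1669, 823.4630, 6579.0080, 0.5287])
        return SelectedModel(design_labels=labels, terms=terms, weights=weights,
                             err_per_term=np.full(5, 0.1), rho=0.005)

    def _table(self, **cols):
        import pandas as pd

        base = {lab: [0.0] for lab in CANONICAL_LABELS}
        base.update({k: [v] for k, v in cols.items()})
        return pd.DataFrame(base)

    def test_all_zero_row_predicts_zero(self):
        assert predict(self.publication_model(), self._table())[0] == pytest.approx(0.0)

    def test_single_term_product(self):
        model = self.publication_model()
        assert predict(model, self._table(pka=1.0))[0] == pytest.approx(0.5287)

    def test_hand_dot_product(self):
        model = self.publication_model()
        row = self._table(e_homo=-1.0, e_lumo=-1.0, omega=1.0, delta_n=1.0)
        assert predict(model, row)[0] == pytest.approx(4976.5371)

    def test_label_mismatch_signals(self):
        model = self.publication_model()
        import pandas as pd

        with pytest.raises(KeyError, match="omega"):
            predict(model, pd.DataFrame({"pka": [1.0]}))


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5))
        y = X @ np.array([0.1, 0.0, -2.7, 0.0, 1e-3]) + 0.01 * rng.normal(size=20)
        D = DesignMatrix(labels=tuple("abcde"), columns=X, response=y)
        model = frols_select(D, rho=0.0, min_gain=0.0)
        clone = SelectedModel.from_json(model.to_json())
        assert clone.terms == model.terms
        assert clone.design_labels == model.design_labels
        assert np.array_equal(clone.weights, model.weights)
        assert np.array_equal(clone.err_per_term, model.err_per_term)
        assert clone.rho == model.rho
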