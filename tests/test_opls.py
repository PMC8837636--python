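"""OPLS-DA, S-plot statistics, marker selection and permutation tests."""

import numpy as np
import pytest

from desimilk.opls import (
    OPLSDA,
    encode_y,
    fit_opls,
    opls_q2,
    permutation_test,
    s_plot,
    select_marker_values,
    select_markers,
)


def _pls1_oracle(X, y):
    """Textbook single-component NIPALS PLS1 (independent of the package)."""
    y = y - y.mean()
    w = X.T @ y
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    c = t @ y / (t @ t)
    return w, t, p, c


def _two_class(rng, n=24, p=15, sep=3.0, n_orth_var=0):
    y = np.array([-1.0, 1.0] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += sep * y  # predictive structure in column 0
    if n_orth_var:
        # strong variation uncorrelated with y
        g = rng.normal(size=n)
        g -= g @ y / (y @ y) * y
        X[:, 1] += 6 * g
    X = X - X.mean(axis=0)
    return X, y


class TestEncodeY:
    def test_cow_convention(self):
        np.testing.assert_array_equal(encode_y(["cow", "goat", "oat"]), [-1, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            encode_y(["cow", "cow"])

    def test_unassigned_label_rejected(self):
        with pytest.raises(ValueError):
            encode_y(["cow", "goat", "yak"], negative_classes=("cow",),
                     positive_classes=("goat",))


class TestFit:
    def test_perfectly_predictive_column(self, rng):
        X, y = _two_class(rng, sep=50.0)
        res = fit_opls(X, y, n_orth=0)
        assert res.r2y >= 0.999

    def test_matches_pls1_oracle_without_orthogonal_removal(self, rng):
        for _ in range(5):
            X = rng.normal(size=(10, 6))
            X = X - X.mean(axis=0)
            y = np.array([-1.0, 1.0] * 5)
            res = fit_opls(X, y, n_orth=0)
            w, t, p, c = _pls1_oracle(X, y)
            np.testing.assert_allclose(res.w, w, atol=1e-8)
            np.testing.assert_allclose(res.t, t, atol=1e-8)
            np.testing.assert_allclose(res.p, p, atol=1e-8)
            assert res.c == pytest.approx(c, abs=1e-8)

    def test_orthogonality_invariants(self, rng):
        X, y = _two_class(rng, n_orth_var=1)
        res = fit_opls(X, y, n_orth=2)
        yc = y - y.mean()
        for w_o, t_o in zip(res.w_orth, res.t_orth):
            assert abs(res.w @ w_o) <= 1e-8
            assert abs(np.corrcoef(t_o, yc)[0, 1]) <= 1e-6

    def test_orthogonal_removal_improves_q2_with_structured_noise(self):
        deltas = []
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            X, y = _two_class(rng, n=28, sep=1.2, n_orth_var=1)
            q0 = opls_q2(X, y, n_orth=0, seed=i)
            q1 = opls_q2(X, y, n_orth=1, seed=i)
            deltas.append(q1 - q0)
        assert np.median(deltas) >= 0

    def test_coefficient_path_equals_scores_path(self, rng):
        X, y = _two_class(rng, n_orth_var=1)
        res = fit_opls(X, y, n_orth=2)
        np.testing.assert_allclose(res.predict(X), res.predict_via_coefficients(X),
                                   atol=1e-8)

    def test_single_predictive_column_coefficients_localised(self, rng):
        n = 20
        y = np.array([-1.0, 1.0] * (n // 2))
        X = np.zeros((n, 8))
        X[:, 3] = 2 * y
        res = fit_opls(X, y, n_orth=0)
        assert abs(res.coefficients[3]) > 0.1
        others = np.delete(res.coefficients, 3)
        assert np.max(np.abs(others)) <= 1e-8

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            OPLSDA(X, np.ones(6))
        with pytest.raises(ValueError):
            OPLSDA(X, np.array([-1.0, 1.0] * 3), n_orth=-1)


class TestQ2:
    def test_separated_classes_strongly_predictive(self, rng):
        X, y = _two_class(rng, sep=5.0)
        assert opls_q2(X, y, n_orth=1, seed=0) > 0.5

    def test_permuted_labels_not_predictive(self):
        q2s = []
        for i in range(20):
            rng = np.random.default_rng(200 + i)
            X, y = _two_class(rng, sep=3.0)
            yp = rng.permutation(y)
            q2s.append(opls_q2(X, yp, n_orth=0, seed=i))
        assert np.median(q2s) <= 0

    def test_deterministic_under_seed(self, rng):
        X, y = _two_class(rng)
        assert opls_q2(X, y, seed=5) == opls_q2(X, y, seed=5)

    def test_fold_larger_than_class_rejected(self, rng):
        X, y = _two_class(rng, n=8)
        with pytest.raises(ValueError):
            opls_q2(X, y, folds=7)


class TestRelabelling:
    def test_sign_flip_antisymmetry(self, rng):
        X, y = _two_class(rng, sep=2.0)
        a = fit_opls(X, y, n_orth=1)
        b = fit_opls(X, -y, n_orth=1)
        assert a.r2y == pytest.approx(b.r2y, abs=1e-10)
        sa, sb = s_plot(a, X), s_plot(b, X)
        np.testing.assert_allclose(sa.p1, -sb.p1, atol=1e-10)
        np.testing.assert_allclose(sa.pcorr, -sb.pcorr, atol=1e-10)
        assert opls_q2(X, y, seed=3) == pytest.approx(opls_q2(X, -y, seed=3), abs=1e-10)


class TestSPlot:
    def test_bin_identical_to_score(self, rng):
        X, y = _two_class(rng, sep=4.0)
        res = fit_opls(X, y, n_orth=0)
        X2 = np.column_stack([X, res.t])
        s = s_plot(res, X2)
        assert s.pcorr[-1] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_bin(self, rng):
        X, y = _two_class(rng)
        res = fit_opls(X, y, n_orth=0)
        X2 = np.column_stack([X, np.zeros(len(y))])
        s = s_plot(res, X2)
        assert s.p1[-1] == 0.0 and s.pcorr[-1] == 0.0

    def test_planted_cow_bin_negative_under_cow_minus_one(self, rng):
        n = 40
        labels = np.array(["cow"] * (n // 2) + ["oat"] * (n // 2))
        y = encode_y(labels)
        X = rng.normal(size=(n, 30))
        X[:, 5] -= 3 * y  # enriched where y = -1 (cow)
        X = X - X.mean(axis=0)
        res = fit_opls(X, y, n_orth=0)
        s = s_plot(res, X)
        assert s.p1[5] < 0 and s.pcorr[5] < -0.5

    def test_coefficient_signs_match_splot_signs(self, rng):
        X, y = _two_class(rng, n=40, sep=3.0)
        res = fit_opls(X, y, n_orth=1)
        s = s_plot(res, X)
        sel = select_markers(s, pcorr_min=0.5, p1_min=0.0)
        for i in np.flatnonzero(sel.mask):
            assert np.sign(res.coefficients[i]) == np.sign(s.pcorr[i])


class TestSelection:
    def test_bundled_table_reproduces_28_markers(self, marker_table):
        sel = select_marker_values([r.p1 for r in marker_table],
                                   [r.pcorr for r in marker_table])
        assert sel.n_selected == 28
        assert len(sel.negative_idx) == 23
        assert len(sel.positive_idx) == 5

    def test_impossible_pcorr_threshold_selects_nothing(self, marker_table):
        sel = select_marker_values([r.p1 for r in marker_table],
                                   [r.pcorr for r in marker_table],
                                   pcorr_min=1.1, p1_min=0.0)
        assert sel.n_selected == 0

    def test_negative_thresholds_rejected(self, rng):
        X, y = _two_class(rng)
        s = s_plot(fit_opls(X, y, 0), X)
        with pytest.raises(ValueError):
            select_markers(s, pcorr_min=-0.1)


class TestPermutation:
    def test_separated_classes_validate(self, rng):
        X, y = _two_class(rng, n=28, sep=4.0)
        rep = permutation_test(X, y, n_orth=0, n_perm=20, seed=0)
        assert rep.valid
        assert np.all(rep.perm_correlation < 1.0)

    def test_minimum_permutations_enforced(self, rng):
        X, y = _two_class(rng)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=5)

    def test_report_carries_distributions(self, rng):
        X, y = _two_class(rng, sep=4.0)
        rep = permutation_test(X, y, n_orth=0, n_perm=12, seed=1)
        assert len(rep.perm_q2) == 12 and len(rep.perm_r2y) == 12
        assert rep.original_r2y >= rep.perm_r2y.min()
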