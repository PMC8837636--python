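"""Principal component analysis with cross-validated predictive ability.

The model quality conventions are the chemometric ones: R2X is the
fraction of (column-centred) data variance captured per component, Q2
the fraction predicted under cross-validation.  Q2 uses row-wise k-fold
deletion where, within each held-out row, variables are split into
interleaved groups and each group is predicted from component scores
estimated on the complementary variables only.  Predicting elements that
did not participate in their own score estimate is what allows Q2 to go
negative on structureless data; plain projection of complete held-out
rows cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FeatureMatrix


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| element of each loading positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


class PCA:
    """Principal component model of a feature matrix.

    Parameters
    ----------
    X : FeatureMatrix or array-like, shape (n_samples, n_bins)
        Rows are (scaled) spectra.  Columns are centred internally; the
        centring vector is retained for projecting new data.
    """

    def __init__(self, X):
        self.X = _as_array(X)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")

    def fit(self, n_components: int) -> "PCAResults":
        n, p = self.X.shape
        max_k = min(n - 1, p)
        if not 1 <= n_components <= max_k:
            raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
        means = self.X.mean(axis=0)
        Xc = self.X - means
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = float(np.sum(s**2))
        explained_all = s**2 / total if total > 0 else np.zeros_like(s)
        loadings = _fix_signs(Vt[:n_components].T)
        scores = Xc @ loadings
        return PCAResults(
            model=self,
            loadings=loadings,
            scores=scores,
            explained=explained_all[:n_components],
            column_means=means,
            _singular_values=s,
        )


@dataclass
class PCAResults:
    """Fitted principal components.

    ``explained`` is R2X per component; ``r2x_cumulative`` the running
    total.  ``q2`` computes the cross-validated per-component Q2.
    """

    model: PCA
    loadings: np.ndarray  # bins x k, orthonormal
    scores: np.ndarray  # samples x k
    explained: np.ndarray  # per-component R2X
    column_means: np.ndarray
    _singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def r2x_cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def project(self, X_new) -> np.ndarray:
        """Scores of new rows (same grid and scaling as the training data)."""
        X_new = _as_array(X_new)
        if X_new.shape[-1] != self.loadings.shape[0]:
            raise ValueError("column count mismatch with training matrix")
        return (X_new - self.column_means) @ self.loadings

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        k = k or self.n_components
        return self.column_means + self.scores[:, :k] @ self.loadings[:, :k].T

    def q2(self, folds: int = 7, var_groups: int = 7, seed: int = 0) -> np.ndarray:
        return pca_q2(self.model.X, self.n_components, folds=folds,
                      var_groups=var_groups, seed=seed)

    def summary(self) -> str:
        lines = ["PCA model", f"  rows: {self.model.X.shape[0]}  bins: {self.model.X.shape[1]}",
                 "  comp   R2X     R2X(cum)"]
        for i, (e, c) in enumerate(zip(self.explained, self.r2x_cumulative), 1):
            lines.append(f"  {i:>4d}  {e:6.4f}  {c:6.4f}")
        return "\n".join(lines)


def pca_q2(X, k: int, folds: int = 7, var_groups: int = 7, seed: int = 0) -> np.ndarray:
    """Cumulative Q2 for components 1..k by row-wise k-fold deletion.

    For every held-out row, each interleaved variable group is predicted
    from least-squares component scores estimated on the other variable
    groups, using loadings fitted without the row.  Q2_k = 1 - PRESS_k/SS
    with SS the total squared deviation of held-out rows from the
    training column means.
    """
    X = _as_array(X)
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed rows ({n})")
    rng = np.random.default_rng(seed)
    row_fold = rng.permutation(n) % folds
    vg = np.arange(p) % var_groups
    press = np.zeros(k)
    ss = 0.0
    for f in range(folds):
        train, test = X[row_fold != f], X[row_fold == f]
        if len(train) < 2 or len(test) == 0:
            continue
        mu = train.mean(axis=0)
        _, _, Vt = np.linalg.svd(train - mu, full_matrices=False)
        V = Vt[:k].T  # p x k
        Tc = test - mu
        ss += float(np.sum(Tc**2))
        for g in range(var_groups):
            obs, mis = vg != g, vg == g
            if not mis.any():
                continue
            for kk in range(1, k + 1):
                Vo = V[obs, :kk]
                # least-squares scores from observed variables only
                scores, *_ = np.linalg.lstsq(Vo, Tc[:, obs].T, rcond=None)
                pred = (V[mis, :kk] @ scores).T
                press[kk - 1] += float(np.sum((Tc[:, mis] - pred) ** 2))
    if ss == 0:
        return np.zeros(k)
    return 1.0 - press / ss
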