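"""Binary OPLS-DA: orthogonal-variation filtering, R2Y/Q2, permutation
validation, S-plot statistics and threshold-based marker selection.

The predictive component is a single NIPALS PLS component fitted after
iteratively removing ``n_orth`` components orthogonal to the class
response; with ``n_orth = 0`` the model reduces exactly to textbook
single-component PLS1.  Class encoding follows the milk convention:
cow = -1, everything else = +1, so cow-enriched bins acquire negative
S-plot statistics.

S-plot scales
-------------
``p1`` is the covariance of each (scaled) bin with the predictive score
t, cov(t, x_i) = t'x_i/(N-1); ``pcorr`` the Pearson correlation.  The
covariance carries the units of X, so ``p1_model`` additionally stores
the covariance rescaled by 1/var(t) — the predictive loading, which is
the dimensionless scale on which the conventional influence threshold
|p1| >= 0.05 is calibrated.  ``select_markers`` thresholds pcorr and,
by default, the model-scale p1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pca import _as_array

DEFAULT_PCORR_MIN = 0.5
DEFAULT_P1_MIN = 0.05


def encode_y(labels, negative_classes=("cow",), positive_classes=None) -> np.ndarray:
    """Encode class labels as a +/-1 response (cow = -1, others = +1).

    Exactly two groups must result; a label falling in neither group is
    an error.
    """
    labels = np.asarray(labels)
    neg = set(negative_classes)
    pos = None if positive_classes is None else set(positive_classes)
    y = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab in neg:
            y[i] = -1.0
        elif pos is None or lab in pos:
            y[i] = +1.0
        else:
            raise ValueError(f"label {lab!r} in neither class group")
    if len(np.unique(y)) != 2:
        raise ValueError("encoding must produce exactly two groups")
    return y


class OPLSDA:
    """Orthogonal PLS discriminant model for a two-group contrast.

    Parameters
    ----------
    X : array or FeatureMatrix, column-centred (typically Pareto-scaled)
    y : +/-1 response vector (see :func:`encode_y`)
    n_orth : number of orthogonal components removed before the
        predictive component is fitted (default 1)
    """

    def __init__(self, X, y, n_orth: int = 1):
        self.X = _as_array(X)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")
        if np.var(self.y) == 0:
            raise ValueError("y has zero variance")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        self.n_orth = n_orth

    def fit(self) -> "OPLSDAResults":
        y_mean = float(self.y.mean())
        y = self.y - y_mean
        Xd = self.X.copy()
        W_o, T_o, P_o = [], [], []
        for _ in range(self.n_orth):
            w = Xd.T @ y
            w /= np.linalg.norm(w)
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-12:
                break  # no orthogonal variation left
            w_o /= nrm
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
        w = Xd.T @ y
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = float(t @ y / (t @ t))
        resid = y - c * t
        r2y = 1.0 - float(resid @ resid) / float(y @ y)
        # regression vector in the original bin space: b = c * [prod(I - w_o p_o')] w
        v = w.copy()
        for w_o, p_o in reversed(list(zip(W_o, P_o))):
            v = v - w_o * (p_o @ v)
        return OPLSDAResults(
            model=self, y_mean=y_mean, w=w, t=t, p=p, c=c,
            w_orth=W_o, t_orth=T_o, p_orth=P_o, r2y=r2y, coefficients=c * v,
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA components and diagnostics."""

    model: OPLSDA
    y_mean: float
    w: np.ndarray  # predictive weights, unit norm
    t: np.ndarray  # predictive scores
    p: np.ndarray  # predictive loadings
    c: float  # y-loading
    w_orth: list
    t_orth: list
    p_orth: list
    r2y: float
    coefficients: np.ndarray
    q2y: float | None = None

    @property
    def n_orth(self) -> int:
        return len(self.w_orth)

    def filter_orthogonal(self, X_new) -> np.ndarray:
        """Remove the fitted orthogonal variation from new (scaled) rows."""
        Xd = np.atleast_2d(_as_array(X_new)).copy()
        for w_o, p_o in zip(self.w_orth, self.p_orth):
            t_o = Xd @ w_o
            Xd -= np.outer(t_o, p_o)
        return Xd

    def predict(self, X_new) -> np.ndarray:
        """Continuous class prediction (around -1/+1) via the scores path."""
        t_new = self.filter_orthogonal(X_new) @ self.w
        return self.c * t_new + self.y_mean

    def predict_via_coefficients(self, X_new) -> np.ndarray:
        """Same prediction through the folded regression vector."""
        return np.atleast_2d(_as_array(X_new)) @ self.coefficients + self.y_mean

    def s_plot(self, X_scaled=None) -> "SPlotResult":
        return s_plot(self, self.model.X if X_scaled is None else X_scaled)

    def summary(self) -> str:
        q2 = f"{self.q2y:.4f}" if self.q2y is not None else "not computed"
        return "\n".join([
            "OPLS-DA model (binary, cow = -1 convention)",
            f"  rows: {len(self.t)}  bins: {len(self.w)}",
            f"  orthogonal components removed: {self.n_orth}",
            f"  R2Y: {self.r2y:.4f}   Q2Y: {q2}",
        ])


def fit_opls(X, y, n_orth: int = 1) -> OPLSDAResults:
    """Convenience wrapper: ``OPLSDA(X, y, n_orth).fit()``."""
    return OPLSDA(X, y, n_orth).fit()


def opls_q2(X, y, n_orth: int = 1, folds: int = 7, seed: int = 0) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS over stratified k-fold held-out
    predictions of the +/-1 response."""
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(y), dtype=int)
    # one global permutation, folds dealt per class along it: the fold
    # structure depends only on class membership, not on label signs
    perm = rng.permutation(len(y))
    for cls in np.unique(y):
        idx = perm[y[perm] == cls]
        if folds > len(idx):
            raise ValueError(f"fold count {folds} exceeds class size {len(idx)}")
        fold_id[idx] = np.arange(len(idx)) % folds
    press = ss = 0.0
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        mu = X[tr].mean(axis=0)
        res = OPLSDA(X[tr] - mu, y[tr], n_orth).fit()
        pred = res.predict(X[te] - mu)
        press += float(np.sum((y[te] - pred) ** 2))
        ss += float(np.sum((y[te] - y[tr].mean()) ** 2))
    return 1.0 - press / ss


@dataclass
class PermutationReport:
    """Y-permutation validation of an OPLS-DA model.

    ``valid`` is true when every permuted-label Q2 falls below the
    original model's Q2; the regression intercepts of R2Y and Q2 against
    label correlation are reported for reference but do not decide the
    flag.
    """

    n_perm: int
    original_r2y: float
    original_q2: float
    perm_correlation: np.ndarray
    perm_r2y: np.ndarray
    perm_q2: np.ndarray
    r2_intercept: float
    q2_intercept: float

    @property
    def valid(self) -> bool:
        return bool(np.all(self.perm_q2 < self.original_q2))

    def summary(self) -> str:
        return "\n".join([
            f"Permutation test ({self.n_perm} label permutations)",
            f"  original R2Y {self.original_r2y:.4f}   Q2 {self.original_q2:.4f}",
            f"  permuted Q2 max {self.perm_q2.max():.4f}"
            f"   (intercepts: R2 {self.r2_intercept:.3f}, Q2 {self.q2_intercept:.3f})",
            f"  model valid: {self.valid}",
        ])


def permutation_test(X, y, n_orth: int = 1, n_perm: int = 100, folds: int = 7,
                     seed: int = 0) -> PermutationReport:
    """Refit the model under random label permutations.

    The identity permutation is excluded; permuted R2Y/Q2 are regressed
    on the absolute correlation between permuted and true labels to
    report the conventional intercepts.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    orig = OPLSDA(X, y, n_orth).fit()
    orig_q2 = opls_q2(X, y, n_orth, folds=folds, seed=seed)
    corr, r2s, q2s = [], [], []
    for i in range(n_perm):
        while True:
            yp = rng.permutation(y)
            if not np.array_equal(yp, y):
                break
        assert not np.array_equal(yp, y)
        res = OPLSDA(X, yp, n_orth).fit()
        try:
            q2p = opls_q2(X, yp, n_orth, folds=folds, seed=seed + 1 + i)
        except ValueError:
            q2p = float("nan")
        corr.append(abs(float(np.corrcoef(yp, y)[0, 1])))
        r2s.append(res.r2y)
        q2s.append(q2p)
    corr_a = np.array(corr)
    r2_a, q2_a = np.array(r2s), np.array(q2s)
    # conventional intercepts: line through permuted points plus the original at corr=1
    cx = np.concatenate([corr_a, [1.0]])
    r2_int = float(np.polyfit(cx, np.concatenate([r2_a, [orig.r2y]]), 1)[1])
    q2_int = float(np.polyfit(cx, np.concatenate([q2_a, [orig_q2]]), 1)[1])
    return PermutationReport(
        n_perm=n_perm, original_r2y=orig.r2y, original_q2=orig_q2,
        perm_correlation=corr_a, perm_r2y=r2_a, perm_q2=q2_a,
        r2_intercept=r2_int, q2_intercept=q2_int,
    )


@dataclass
class SPlotResult:
    """Per-bin S-plot statistics for a fitted predictive component."""

    p1: np.ndarray  # cov(t, x_i), units of X
    pcorr: np.ndarray  # corr(t, x_i), dimensionless
    p1_model: np.ndarray  # p1 / var(t): predictive loading scale
    bin_centers: np.ndarray | None = None


def s_plot(results: OPLSDAResults, X_scaled, bin_centers=None) -> SPlotResult:
    """Covariance and correlation of every bin with the predictive score.

    Zero-variance bins get p1 = pcorr = 0.  Sample (N-1) conventions
    throughout.
    """
    X = _as_array(X_scaled)
    t = results.t
    n = len(t)
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    p1 = Xc.T @ tc / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = Xc.std(axis=0, ddof=1)
    pcorr = np.zeros_like(p1)
    ok = sd_x > 0
    pcorr[ok] = p1[ok] / (sd_t * sd_x[ok])
    p1 = np.where(ok, p1, 0.0)
    var_t = sd_t**2
    return SPlotResult(p1=p1, pcorr=pcorr, p1_model=p1 / var_t,
                       bin_centers=None if bin_centers is None else np.asarray(bin_centers))


@dataclass
class SelectedMarkers:
    """Bins passing the reliability/influence thresholds, split by sign.

    Negative-sign bins are cow-associated under the cow = -1 encoding;
    positive-sign bins belong to the other group.
    """

    mask: np.ndarray
    pcorr: np.ndarray
    negative_idx: np.ndarray = field(init=False)
    positive_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sel = np.flatnonzero(self.mask)
        self.negative_idx = sel[self.pcorr[sel] < 0]
        self.positive_idx = sel[self.pcorr[sel] >= 0]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def select_markers(s: SPlotResult, pcorr_min: float = DEFAULT_PCORR_MIN,
                   p1_min: float = DEFAULT_P1_MIN, p1_scale: str = "model") -> SelectedMarkers:
    """Bins with |pcorr| >= pcorr_min and |p1| >= p1_min.

    Thresholds are inclusive; ``p1_scale`` chooses whether the influence
    threshold applies to the model-scale loading (default) or the raw
    covariance.
    """
    if pcorr_min < 0 or p1_min < 0:
        raise ValueError("thresholds must be >= 0")
    p1 = s.p1_model if p1_scale == "model" else s.p1
    return select_marker_values(p1, s.pcorr, pcorr_min, p1_min)


def select_marker_values(p1, pcorr, pcorr_min: float = DEFAULT_PCORR_MIN,
                         p1_min: float = DEFAULT_P1_MIN) -> SelectedMarkers:
    """Apply the thresholds directly to given (p1, pcorr) value arrays,
    e.g. the bundled marker table's printed statistics."""
    p1 = np.asarray(p1, dtype=float)
    pcorr = np.asarray(pcorr, dtype=float)
    mask = (np.abs(pcorr) >= pcorr_min) & (np.abs(p1) >= p1_min)
    return SelectedMarkers(mask=mask, pcorr=pcorr)


def opls_coefficients(results: OPLSDAResults) -> np.ndarray:
    """Per-bin regression coefficients b with y_hat = X b + y_mean."""
    return results.coefficients
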