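"""PCA-subspace Fisher discriminant analysis with Mahalanobis outlier
rejection and leave-20%-out bootstrap correct-classification rates.

The classifier mirrors the modelling chain used for ambient-MS milk
authentication: spectra are first projected onto enough principal
components to capture most of the variance, Fisher discriminant axes are
fitted in that subspace, and held-out spectra are assigned to the class
with the smallest Mahalanobis distance (pooled within-class covariance).
A spectrum whose nearest-class distance exceeds ``outlier_sigma``
standard deviations is flagged as an outlier; classification rates are
reported both excluding and including outliers because it is ambiguous
which denominator legacy chemometrics packages use.

Bootstrap validation splits at the *sample* level (all replicate scans
of a sample stay on one side) but counts correctness at the *spectrum*
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .pca import PCA, PCAResults, _as_array, _fix_signs
from .preprocess import FeatureMatrix

DEFAULT_OUTLIER_SIGMA = 5.0
DEFAULT_R2X_TARGET = 0.95
DEFAULT_MAX_PCS = 60


def choose_n_pcs(explained: np.ndarray, r2x_target: float = DEFAULT_R2X_TARGET,
                 cap: int = DEFAULT_MAX_PCS) -> int:
    """Smallest component count with cumulative R2X >= target, capped."""
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, r2x_target) + 1)
    return max(1, min(k, len(explained), cap))


class PCALDA:
    """Fisher LDA in a principal-component subspace.

    Parameters
    ----------
    X : FeatureMatrix or array
        Scaled feature matrix (rows may be per-sample averages or
        individual spectra).
    labels : array-like of str, optional
        Class labels; defaults to the species column of ``X``'s metadata.
    n_pcs : int, optional
        PCA subspace dimension; default is the smallest count capturing
        ``r2x_target`` of the variance, capped at ``max_pcs``.
    """

    def __init__(self, X, labels=None, n_pcs: int | None = None,
                 r2x_target: float = DEFAULT_R2X_TARGET, max_pcs: int = DEFAULT_MAX_PCS,
                 outlier_sigma: float = DEFAULT_OUTLIER_SIGMA, ridge: float = 1e-8,
                 covariance: str = "pooled"):
        if covariance not in ("pooled", "per_class"):
            raise ValueError(f"unknown covariance mode {covariance!r}")
        if labels is None:
            if not isinstance(X, FeatureMatrix):
                raise ValueError("labels required when X is a bare array")
            labels = X.labels
        self.X = _as_array(X)
        self.labels = np.asarray(labels)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must match matrix rows")
        self.classes = np.unique(self.labels)
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        counts = pd.Series(self.labels).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"classes with < 2 rows: {small}")
        self.n_pcs = n_pcs
        self.r2x_target = r2x_target
        self.max_pcs = max_pcs
        self.outlier_sigma = outlier_sigma
        self.ridge = ridge
        self.covariance = covariance

    def fit(self) -> "LDAResults":
        n, p = self.X.shape
        full_k = min(n - 1, p, self.max_pcs if self.n_pcs is None else self.n_pcs)
        pca = PCA(self.X).fit(full_k)
        k = self.n_pcs or choose_n_pcs(pca.explained, self.r2x_target, self.max_pcs)
        k = min(k, full_k)
        scores = pca.scores[:, :k]

        # Fisher: maximise between/within variance ratio in the PC subspace
        overall = scores.mean(axis=0)
        Sw = np.zeros((k, k))
        Sb = np.zeros((k, k))
        for cls in self.classes:
            sub = scores[self.labels == cls]
            mu = sub.mean(axis=0)
            d = sub - mu
            Sw += d.T @ d
            m = (mu - overall)[:, None]
            Sb += len(sub) * (m @ m.T)
        Sw_reg = Sw + self.ridge * (np.trace(Sw) / k + 1.0) * np.eye(k)
        evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
        order = np.argsort(evals)[::-1][: len(self.classes) - 1]
        directions = _fix_signs(evecs[:, order])

        z = scores @ directions
        class_means = {cls: z[self.labels == cls].mean(axis=0) for cls in self.classes}
        resid = np.concatenate([z[self.labels == cls] - class_means[cls] for cls in self.classes])
        dof = max(len(z) - len(self.classes), 1)
        d = directions.shape[1]

        def _reg(cov: np.ndarray) -> np.ndarray:
            return cov + self.ridge * (np.trace(cov) / d + 1.0) * np.eye(d)

        pooled = _reg(resid.T @ resid / dof)
        chols = {}
        if self.covariance == "per_class":
            # heterogeneous classes (e.g. a pooled "adulterated" group
            # spanning many mixing levels) break the equal-covariance
            # assumption; per-class Mahalanobis restores calibration
            for cls in self.classes:
                dc = z[self.labels == cls] - class_means[cls]
                cov = _reg(dc.T @ dc / max(len(dc) - 1, 1))
                chols[cls] = scipy.linalg.cholesky(cov, lower=True)
        else:
            chol = scipy.linalg.cholesky(pooled, lower=True)
            chols = {cls: chol for cls in self.classes}
        return LDAResults(
            model=self, pca=pca, n_pcs=k, directions=directions,
            class_means=class_means, pooled_cov=pooled, _chols=chols,
        )


@dataclass
class LDAResults:
    """Fitted discriminant model: axes, class centroids, pooled covariance."""

    model: PCALDA
    pca: PCAResults
    n_pcs: int
    directions: np.ndarray  # n_pcs x (classes-1)
    class_means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    _chols: dict[str, np.ndarray]

    @property
    def classes(self) -> np.ndarray:
        return self.model.classes

    def transform(self, X_new) -> np.ndarray:
        """Discriminant-space coordinates of new (scaled) spectra."""
        return self.pca.project(X_new)[:, : self.n_pcs] @ self.directions

    def mahalanobis(self, X_new) -> np.ndarray:
        """Distance of each row to each class centroid, in sd units."""
        z = self.transform(np.atleast_2d(_as_array(X_new)))
        out = np.empty((len(z), len(self.classes)))
        for j, cls in enumerate(self.classes):
            d = z - self.class_means[cls]
            w = scipy.linalg.solve_triangular(self._chols[cls], d.T, lower=True)
            out[:, j] = np.sqrt(np.sum(w**2, axis=0))
        return out

    def classify(self, X_new, outlier_sigma: float | None = None,
                 rule: str = "nearest") -> "ClassificationResult":
        """Mahalanobis assignment with outlier flagging.

        ``rule="nearest"`` assigns the class with the smallest distance;
        ``rule="gaussian"`` maximises the Gaussian log-density
        (-d^2/2 - log|Sigma|/2, equal priors), which stays calibrated
        when class covariances differ in spread.  Outliers are always
        flagged on the distance to the nearest centroid.
        """
        sigma = self.model.outlier_sigma if outlier_sigma is None else outlier_sigma
        dist = self.mahalanobis(X_new)
        if rule == "nearest":
            pick = np.argmin(dist, axis=1)
        elif rule == "gaussian":
            logdet = np.array([
                2.0 * np.sum(np.log(np.diag(self._chols[cls]))) for cls in self.classes
            ])
            pick = np.argmin(dist**2 + logdet[None, :], axis=1)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        d_min = dist.min(axis=1)
        return ClassificationResult(
            assigned=self.classes[pick],
            distance=d_min,
            outlier=d_min > sigma,
        )

    def summary(self) -> str:
        lines = [
            "PCA-LDA model",
            f"  classes: {list(self.classes)}",
            f"  PCA components: {self.n_pcs} "
            f"(cumulative R2X {self.pca.r2x_cumulative[self.n_pcs - 1]:.3f})",
            f"  discriminant axes: {self.directions.shape[1]}",
            f"  outlier threshold: {self.model.outlier_sigma} sigma (Mahalanobis)",
        ]
        return "\n".join(lines)


@dataclass
class ClassificationResult:
    """Per-spectrum assignments plus aggregate correct-classification rates."""

    assigned: np.ndarray
    distance: np.ndarray
    outlier: np.ndarray
    truth: np.ndarray | None = None

    def with_truth(self, truth) -> "ClassificationResult":
        self.truth = np.asarray(truth)
        return self

    @property
    def ccr_excluding(self) -> float:
        """Correct / total over non-outlier spectra."""
        keep = ~self.outlier
        if keep.sum() == 0:
            return float("nan")
        return float(np.mean(self.assigned[keep] == self.truth[keep]))

    @property
    def ccr_including(self) -> float:
        """Correct / total over all spectra, outliers judged by assigned class."""
        return float(np.mean(self.assigned == self.truth))


@dataclass
class BootstrapCCR:
    """Aggregate of repeated stratified leave-20%-out validations."""

    repeats: int
    holdout_fraction: float
    n_correct_excl: int = 0
    n_total_excl: int = 0
    n_correct_incl: int = 0
    n_total_incl: int = 0
    n_outliers: int = 0
    per_class: dict = field(default_factory=dict)  # class -> [correct, total] (excl.)
    confusion: dict = field(default_factory=dict)  # (true, assigned) -> count (excl.)

    @property
    def ccr_excluding(self) -> float:
        return self.n_correct_excl / self.n_total_excl if self.n_total_excl else float("nan")

    @property
    def ccr_including(self) -> float:
        return self.n_correct_incl / self.n_total_incl if self.n_total_incl else float("nan")

    def ccr_for(self, cls: str) -> float:
        c, t = self.per_class.get(cls, (0, 0))
        return c / t if t else float("nan")

    def summary(self) -> str:
        lines = [
            f"Bootstrap CCR ({self.repeats} stratified {1 - self.holdout_fraction:.0%}/"
            f"{self.holdout_fraction:.0%} splits, spectrum-level counting)",
            f"  CCR excluding outliers: {100 * self.ccr_excluding:.2f}%"
            f"  ({self.n_correct_excl}/{self.n_total_excl})",
            f"  CCR including outliers: {100 * self.ccr_including:.2f}%"
            f"  ({self.n_correct_incl}/{self.n_total_incl})",
            f"  outliers flagged: {self.n_outliers}",
        ]
        for cls in sorted(self.per_class):
            lines.append(f"    {cls}: {100 * self.ccr_for(cls):.2f}%")
        return "\n".join(lines)


def bootstrap_ccr(
    fm: FeatureMatrix,
    labels=None,
    holdout_fraction: float = 0.2,
    repeats: int = 25,
    seed: int = 0,
    n_pcs: int | None = None,
    outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
    r2x_target: float = DEFAULT_R2X_TARGET,
    max_pcs: int = DEFAULT_MAX_PCS,
) -> BootstrapCCR:
    """Leave-20%-out bootstrap validation of the PCA-LDA classifier.

    Splits are stratified by class and made at the sample level: all
    spectra sharing a sample_id stay together.  Correctness is counted
    per held-out spectrum, both excluding and including flagged
    outliers.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    labels = np.asarray(labels if labels is not None else fm.labels)
    sample_ids = fm.meta["sample_id"].to_numpy()
    uniq = pd.DataFrame({"sample_id": sample_ids, "label": labels}).drop_duplicates("sample_id")
    rng = np.random.default_rng(seed)
    agg = BootstrapCCR(repeats=repeats, holdout_fraction=holdout_fraction)
    for _ in range(repeats):
        test_samples: list[str] = []
        for cls in np.unique(uniq["label"]):
            ids = uniq.loc[uniq["label"] == cls, "sample_id"].to_numpy()
            n_test = max(1, int(round(holdout_fraction * len(ids))))
            if n_test >= len(ids):
                raise ValueError(f"class {cls!r} too small to stratify a {holdout_fraction:.0%} holdout")
            test_samples.extend(rng.choice(ids, size=n_test, replace=False))
        test_mask = np.isin(sample_ids, test_samples)
        assert not (set(sample_ids[test_mask]) & set(sample_ids[~test_mask]))
        res = PCALDA(
            fm.values[~test_mask], labels[~test_mask], n_pcs=n_pcs,
            r2x_target=r2x_target, max_pcs=max_pcs, outlier_sigma=outlier_sigma,
        ).fit()
        pred = res.classify(fm.values[test_mask]).with_truth(labels[test_mask])
        keep = ~pred.outlier
        agg.n_correct_excl += int(np.sum(pred.assigned[keep] == pred.truth[keep]))
        agg.n_total_excl += int(keep.sum())
        agg.n_correct_incl += int(np.sum(pred.assigned == pred.truth))
        agg.n_total_incl += len(pred.assigned)
        agg.n_outliers += int(pred.outlier.sum())
        for cls in np.unique(pred.truth):
            m = (pred.truth == cls) & keep
            c, t = agg.per_class.get(cls, (0, 0))
            agg.per_class[cls] = (c + int(np.sum(pred.assigned[m] == cls)), t + int(m.sum()))
        for tr, asgn in zip(pred.truth[keep], pred.assigned[keep]):
            key = (str(tr), str(asgn))
            agg.confusion[key] = agg.confusion.get(key, 0) + 1
    return agg
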