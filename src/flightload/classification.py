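"""Regularized CSP, shrinkage LDA, mRMR fusion and stratified cross-validation.

The classifier chain follows standard small-sample BCI practice: class
covariances are estimated with automatic Ledoit–Wolf shrinkage toward a
scaled identity; Common Spatial Patterns are the extreme generalized
eigenvectors of Σ_A w = λ (Σ_A + Σ_B) w; the linear discriminant uses the
shrunk pooled covariance, w = Σ⁻¹(μ₁ − μ₀), with the boundary at the
midpoint of the projected class means (equal priors — the classified load
conditions are balanced by design).  Feature fusion selects the top-k
features by greedy minimum-redundancy maximum-relevance mutual
information.  All data-dependent fitting happens inside each training
fold of a stratified five-fold cross-validation; reported metrics are
balanced accuracy, sensitivity and specificity on the held-out folds,
with the high-load class as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .config import BANDS
from .features import BandCovariances, FeatureMatrix
from .recording_io import EpochSet

__all__ = [
    "CSPModel",
    "LDAModel",
    "FoldResult",
    "ClassificationReport",
    "shrink_covariance",
    "fit_csp",
    "fit_csp_from_covariances",
    "fit_slda",
    "mrmr_select",
    "stratified_folds",
    "crossvalidate",
]


def shrink_covariance(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit–Wolf analytic shrinkage toward the scaled identity.

    ``samples`` is (observations × variables).  Returns
    ``(1−λ)·Σ_emp + λ·(tr Σ_emp / p)·I`` with λ the analytic optimum
    clipped to [0, 1]; a zero-variance (degenerate) empirical covariance
    forces λ = 1.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 observations (rows)")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    mu = np.trace(S) / p
    delta = np.sum((S - mu * np.eye(p)) ** 2) / p
    if delta <= 1e-30 * max(mu**2, 1.0):
        lam = 1.0
    else:
        # E||x xᵀ − S||² from the sample: Σ_k ||x_k||⁴ − n·||S||²_F
        beta_sum = float(np.sum(np.sum(Xc**2, axis=1) ** 2) - n * np.sum(S**2))
        beta = beta_sum / (n**2 * p)
        lam = float(np.clip(beta / delta, 0.0, 1.0))
    sigma = (1 - lam) * S + lam * mu * np.eye(p)
    return sigma, lam


@dataclass
class CSPModel:
    """Common Spatial Patterns filters for one frequency band."""

    band: str
    band_edges: tuple[float, float]
    filters: np.ndarray  # channels × 2·n_pairs, extremes first
    eigenvalues: np.ndarray  # associated generalized eigenvalues, in [0, 1]
    class_order: tuple[str, str]
    shrinkage: tuple[float, float]  # mean per-class Ledoit–Wolf λ
    composite_covariance: np.ndarray | None = None  # Σ_A + Σ_B (training)

    def __post_init__(self):
        if np.any(self.eigenvalues < -1e-9) or np.any(self.eigenvalues > 1 + 1e-9):
            raise ValueError("CSP eigenvalues must lie in [0, 1]")


def fit_csp_from_covariances(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    n_pairs: int = 2,
    band: str = "",
    band_edges: tuple[float, float] = (0.0, 0.0),
    class_order: tuple[str, str] = ("low", "high"),
    shrinkage: tuple[float, float] = (0.0, 0.0),
) -> CSPModel:
    """Solve Σ_A w = λ (Σ_A + Σ_B) w and keep the extreme eigenvectors.

    Filters are ordered extremes-first (largest λ, smallest λ, second
    largest, second smallest) and normalized so wᵀ(Σ_A+Σ_B)w = 1.
    """
    comp = cov_a + cov_b
    vals, vecs = eigh(cov_a, comp)  # ascending; b-orthonormal columns
    order = []
    for i in range(n_pairs):
        order.extend([len(vals) - 1 - i, i])  # top-i, bottom-i interleaved
    filters = vecs[:, order]
    return CSPModel(
        band=band,
        band_edges=band_edges,
        filters=filters,
        eigenvalues=np.clip(vals[order], 0.0, 1.0),
        class_order=class_order,
        shrinkage=shrinkage,
        composite_covariance=comp,
    )


def _epoch_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    covs = np.empty((epochs.n_epochs, len(epochs.channel_names),
                     len(epochs.channel_names)))
    lams = np.empty(epochs.n_epochs)
    for i in range(epochs.n_epochs):
        covs[i], lams[i] = shrink_covariance(epochs.data[i].T)
    return covs, lams


def fit_csp(
    epochs_a: EpochSet, epochs_b: EpochSet, n_pairs: int = 2, band: str = ""
) -> CSPModel:
    """Fit CSP from two classes of band-filtered epochs.

    Per class, the per-epoch Ledoit–Wolf-shrunk covariances are averaged
    before the generalized eigendecomposition.
    """
    if epochs_a.channel_names != epochs_b.channel_names:
        raise ValueError("channel mismatch between classes")
    if epochs_a.n_epochs < 2 or epochs_b.n_epochs < 2:
        raise ValueError("need at least 2 epochs per class")
    covs_a, lam_a = _epoch_covariances(epochs_a)
    covs_b, lam_b = _epoch_covariances(epochs_b)
    cond_a = str(epochs_a.metadata["condition"].iloc[0])
    cond_b = str(epochs_b.metadata["condition"].iloc[0])
    return fit_csp_from_covariances(
        covs_a.mean(axis=0), covs_b.mean(axis=0), n_pairs,
        band=band, band_edges=BANDS.get(band, (0.0, 0.0)),
        class_order=(cond_a, cond_b),
        shrinkage=(float(lam_a.mean()), float(lam_b.mean())),
    )


@dataclass
class LDAModel:
    """Linear discriminant with Ledoit–Wolf-shrunk pooled covariance."""

    weights: np.ndarray
    bias: float
    shrinkage: float
    class_means: tuple[np.ndarray, np.ndarray]  # (negative, positive)
    pooled_covariance: np.ndarray
    classes: tuple[str, str]  # (negative, positive)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        pos = self.decision(X) > 0
        return np.where(pos, self.classes[1], self.classes[0]).astype(object)


def _class_pair(labels: np.ndarray, positive: str | None) -> tuple[str, str]:
    classes = sorted(set(map(str, labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive is None:
        positive = "high" if "high" in classes else classes[1]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not in {classes}")
    negative = next(c for c in classes if c != positive)
    return negative, positive


def fit_slda(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    positive: str | None = None,
    shrinkage: float | None = None,
) -> LDAModel:
    """Fit shrinkage LDA: w = Σ_shrunk⁻¹ (μ₊ − μ₋), midpoint bias.

    λ is the Ledoit–Wolf analytic optimum of the pooled within-class
    scatter unless overridden.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels if labels is None else labels
    else:
        X = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    neg, pos = _class_pair(labels, positive)
    Xn, Xp = X[labels == neg], X[labels == pos]
    mu_n, mu_p = Xn.mean(axis=0), Xp.mean(axis=0)
    centered = np.vstack([Xn - mu_n, Xp - mu_p])
    sigma, lam = shrink_covariance(centered)
    if shrinkage is not None:
        p = X.shape[1]
        emp = centered.T @ centered / len(centered)
        sigma = (1 - shrinkage) * emp + shrinkage * (np.trace(emp) / p) * np.eye(p)
        lam = float(shrinkage)
    try:
        w = np.linalg.solve(sigma, mu_p - mu_n)
    except np.linalg.LinAlgError:
        # degenerate scatter (e.g. constant features): minimum-norm solution
        w = np.linalg.pinv(sigma) @ (mu_p - mu_n)
    b = -0.5 * float(w @ (mu_p + mu_n))
    return LDAModel(w, b, lam, (mu_n, mu_p), sigma, (neg, pos))


def _quantile_bins(col: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, col, side="right")


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    from sklearn.metrics import mutual_info_score

    return float(mutual_info_score(a, b))


def mrmr_select(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 20,
    n_bins: int = 8,
) -> list[int]:
    """Greedy minimum-redundancy maximum-relevance feature selection.

    Features are discretized into equal-frequency bins; the greedy step
    maximizes I(f; y) − mean over selected s of I(f; s).  Deterministic:
    ties break toward the lowest column index.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels if labels is None else labels
    else:
        X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n_feat = X.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds feature count {n_feat}")
    binned = [_quantile_bins(X[:, j], n_bins) for j in range(n_feat)]
    relevance = np.array([_mi(b, labels) for b in binned])

    selected: list[int] = []
    redundancy = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    for step in range(k):
        if step == 0:
            scores = relevance.copy()
        else:
            scores = relevance - redundancy / len(selected)
        scores[~remaining] = -np.inf
        j = int(np.argmax(scores))  # argmax takes the first (lowest) index on ties
        selected.append(j)
        remaining[j] = False
        if step < k - 1:
            mi_j = np.array(
                [_mi(binned[j], binned[m]) if remaining[m] else 0.0
                 for m in range(n_feat)]
            )
            redundancy += mi_j
    return selected


def stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Shuffle once with the run seed, then assign round-robin per class."""
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in sorted(set(map(str, labels))):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} epochs, fewer than "
                f"{n_folds} folds"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


@dataclass
class FoldResult:
    fold: int
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    selected: list[int]
    lda: LDAModel
    csp_bank: dict
    feature_covariance: np.ndarray
    feature_names: list[str]


@dataclass
class ClassificationReport:
    """Fold-wise and aggregate single-trial classification metrics."""

    folds: list[FoldResult]
    fold_assignment: np.ndarray
    feature_names: list[str]
    classes: tuple[str, str]
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def _series(self, attr: str) -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.folds])

    @property
    def balanced_accuracy(self) -> float:
        return float(self._series("balanced_accuracy").mean())

    @property
    def sensitivity(self) -> float:
        return float(self._series("sensitivity").mean())

    @property
    def specificity(self) -> float:
        return float(self._series("specificity").mean())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "seed": int(self.seed),
            "n_folds": len(self.folds),
            "balanced_accuracy": self.balanced_accuracy,
            "balanced_accuracy_sd": float(self._series("balanced_accuracy").std()),
            "sensitivity": self.sensitivity,
            "sensitivity_sd": float(self._series("sensitivity").std()),
            "specificity": self.specificity,
            "specificity_sd": float(self._series("specificity").std()),
            "per_fold": [
                {
                    "fold": f.fold,
                    "balanced_accuracy": f.balanced_accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "selected_features": [self.feature_names[j] for j in f.selected]
                    if f.selected is not None
                    else None,
                }
                for f in self.folds
            ],
            "meta": self.meta,
        }

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": self._series("fold").astype(int),
                "balanced_accuracy": self._series("balanced_accuracy"),
                "sensitivity": self._series("sensitivity"),
                "specificity": self._series("specificity"),
            }
        )


def _fold_metrics(
    truth: np.ndarray, predicted: np.ndarray, classes: tuple[str, str]
) -> tuple[float, float, float]:
    neg, pos = classes
    truth = np.asarray(truth, dtype=object)
    pos_mask = truth == pos
    sens = float(np.mean(predicted[pos_mask] == pos)) if pos_mask.any() else np.nan
    spec = float(np.mean(predicted[~pos_mask] == neg)) if (~pos_mask).any() else np.nan
    return (sens + spec) / 2.0, sens, spec


def _csp_fold_features(
    csp_data: BandCovariances,
    train_idx: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, str],
    n_pairs: int,
) -> tuple[dict, np.ndarray, list[str]]:
    """Fit per-band CSP on the training epochs; emit log-power for all epochs."""
    neg, pos = classes
    bank = {}
    cols, names = [], []
    train_labels = labels[train_idx]
    for band, edges in csp_data.bands.items():
        sh = csp_data.shrunk[band][train_idx]
        cov_a = sh[train_labels == neg].mean(axis=0)
        cov_b = sh[train_labels == pos].mean(axis=0)
        model = fit_csp_from_covariances(
            cov_a, cov_b, n_pairs, band=band, band_edges=edges,
            class_order=(neg, pos),
        )
        bank[band] = model
        emp = csp_data.empirical[band]
        power = np.einsum("cf,ecd,df->ef", model.filters, emp, model.filters)
        cols.append(np.log(np.maximum(power, 1e-300)))
        names.extend(f"pow:{band}:csp{i + 1}" for i in range(model.filters.shape[1]))
    return bank, np.hstack(cols), names


def crossvalidate(
    features: FeatureMatrix | None = None,
    labels: np.ndarray | None = None,
    n_folds: int = 5,
    fusion: int | None = None,
    seed: int = 0,
    csp_data: BandCovariances | None = None,
    n_pairs: int = 2,
    positive: str | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of the sLDA chain.

    ``features`` holds static (fit-free) columns such as ERP samples;
    ``csp_data`` triggers a per-fold CSP refit from cached band
    covariances, so CSP — like mRMR (when ``fusion`` is a k) and the sLDA
    shrinkage — only ever sees training folds.  Sensitivity is defined on
    the high-load (positive) class.
    """
    if features is None and csp_data is None:
        raise ValueError("provide features and/or csp_data")
    if labels is None:
        labels = features.labels if features is not None else csp_data.labels
    labels = np.asarray(labels, dtype=object)
    if features is not None and len(labels) != features.n_epochs:
        raise ValueError("labels/features length mismatch")
    if csp_data is not None and len(labels) != csp_data.n_epochs:
        raise ValueError("labels/csp_data length mismatch")
    classes = _class_pair(labels, positive)

    assignment = stratified_folds(labels, n_folds, seed)
    folds: list[FoldResult] = []
    feature_names: list[str] = []
    for fold in range(n_folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        blocks, names = [], []
        bank: dict = {}
        if features is not None:
            blocks.append(features.values)
            names.extend(features.feature_names)
        if csp_data is not None:
            bank, csp_cols, csp_names = _csp_fold_features(
                csp_data, train_idx, labels, classes, n_pairs
            )
            blocks.append(csp_cols)
            names.extend(csp_names)
        X = np.hstack(blocks)
        feature_names = names

        X_train, y_train = X[train_idx], labels[train_idx]
        X_test, y_test = X[test_idx], labels[test_idx]
        if fusion is not None:
            selected = mrmr_select(X_train, y_train, k=fusion)
            X_train = X_train[:, selected]
            X_test = X_test[:, selected]
        else:
            selected = list(range(X.shape[1]))
        lda = fit_slda(X_train, y_train, positive=classes[1])
        predicted = lda.predict(X_test)
        bacc, sens, spec = _fold_metrics(y_test, predicted, classes)
        feat_cov = np.cov(X_train, rowvar=False)
        folds.append(
            FoldResult(fold, bacc, sens, spec, selected, lda, bank,
                       np.atleast_2d(feat_cov), names)
        )
    report = ClassificationReport(
        folds, assignment, feature_names, classes, seed=seed
    )
    if csp_data is not None:
        report.meta["channel_names"] = list(csp_data.channel_names)
    return report
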