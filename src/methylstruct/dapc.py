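"""Discriminant analysis of principal components (DAPC).

DAPC summarizes a high-dimensional methylation matrix by PCA, then runs a
canonical linear discriminant analysis on the retained principal
components.  Following the K-1 rule, exactly one fewer component than the
number of groups is retained by default: for K effective groups, K-1 axes
suffice to carry all between-group variation.

The discriminant step maximizes the ratio of between- to within-group
variance on the retained PCs (generalized eigenproblem with the pooled
within-group covariance), with equal group priors.  Per-marker loadings on
each discriminant axis are the composition of the PCA loadings with the
discriminant vectors, so ``X_centered @ marker_loadings`` reproduces the
individual scores exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .transforms import HellingerMatrix, center_columns

__all__ = [
    "PcaModel",
    "DapcModel",
    "AxisSignificance",
    "fit_pca",
    "fit_dapc",
    "assignment_accuracy",
    "axis_significance",
]

logger = logging.getLogger(__name__)

_EPS_FRACTION = 1e-8  # within-covariance ridge, relative to mean diagonal


@dataclass
class PcaModel:
    """Orthonormal component loadings, eigenvalues and centering means."""

    loadings: np.ndarray  # (n_markers, n_components), orthonormal columns
    eigenvalues: np.ndarray  # descending, >= 0 (variance units)
    means: np.ndarray  # column means used for centering

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) @ self.loadings


@dataclass
class DapcModel:
    """Fitted DAPC: PC basis, discriminant axes, scores and centroids."""

    pca: PcaModel
    n_retained_pcs: int
    disc_axes: np.ndarray  # (n_pcs, n_das) vectors in PC space
    disc_eigenvalues: np.ndarray  # descending
    scores: np.ndarray  # (n_individuals, n_das)
    marker_loadings: np.ndarray  # (n_markers, n_das)
    groups: np.ndarray  # unique group labels, sorted
    labels: np.ndarray  # per-individual labels used in the fit
    centroids: np.ndarray  # (n_groups, n_das) in discriminant space
    within_cov: np.ndarray  # pooled within-group covariance in PC space
    markers: list[str] | None = None
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.disc_axes.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (raw, uncentered) data rows into discriminant space."""
        return (np.asarray(X, dtype=float) - self.pca.means) @ self.marker_loadings

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-posterior group per row: equal priors, Gaussian with the
        pooled within-group covariance, which is spherical in discriminant
        space by construction — hence nearest centroid."""
        scores = self.transform(X)
        d2 = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return self.groups[np.argmin(d2, axis=1)]


@dataclass
class AxisSignificance:
    """Per-discriminant-axis group-effect test (one-way linear model)."""

    f_statistic: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray  # Benjamini-Hochberg step-up across axes
    significant: np.ndarray  # q < alpha
    degenerate: np.ndarray  # constant-score axes (p set to 1)
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each column positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_pca(X_centered: np.ndarray, n_components: int) -> PcaModel:
    """PCA of an already column-centered matrix via SVD.

    Components are ordered by decreasing eigenvalue (variance explained,
    ``s**2 / (n-1)``); the sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    X = np.asarray(X_centered, dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={max_comp}"
        )
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:n_components].T
    eigenvalues = (s[:n_components] ** 2) / (n - 1)
    signs = _fix_signs(loadings)
    return PcaModel(loadings=loadings * signs, eigenvalues=eigenvalues, means=np.zeros(p))


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, HellingerMatrix):
        return np.asarray(X.values, dtype=float), list(X.markers)
    return np.asarray(X, dtype=float), None


def fit_dapc(
    X,
    labels,
    n_pcs: int | None = None,
    n_das: int | None = None,
) -> DapcModel:
    """Fit PCA followed by canonical LDA on the retained components.

    Parameters
    ----------
    X
        :class:`~methylstruct.transforms.HellingerMatrix` or plain numeric
        matrix (individuals x markers); centering is done internally.
    labels
        Group label per individual; every group needs >= 2 members.
    n_pcs
        Principal components retained for the discriminant step.  Default
        K-1; capped at the matrix rank with a logged warning.
    n_das
        Discriminant axes kept (<= min(n_pcs, K-1)); default K-1.
    """
    values, markers = _as_matrix(X)
    labels = np.asarray(labels)
    groups, inv = np.unique(labels, return_inverse=True)
    K = len(groups)
    if K < 2:
        raise ValueError("DAPC requires at least 2 groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        bad = groups[int(np.argmin(counts))]
        raise ValueError(f"group {bad!r} has fewer than 2 members")

    centered, means, zero_var = center_columns(values)
    dropped = (
        [markers[j] for j in np.flatnonzero(zero_var)] if markers is not None else []
    )
    if zero_var.any():
        logger.warning("dropping %d zero-variance markers before PCA", int(zero_var.sum()))
    keep = ~zero_var
    Xc = centered[:, keep]

    n = values.shape[0]
    rank = min(n - 1, Xc.shape[1])
    want_pcs = (K - 1) if n_pcs is None else n_pcs
    if want_pcs > rank:
        logger.warning("requested %d PCs but rank is %d; retaining %d", want_pcs, rank, rank)
        want_pcs = rank
    if want_pcs < 1:
        raise ValueError("cannot retain fewer than one principal component")
    pca_kept = fit_pca(Xc, want_pcs)

    # re-inflate loadings/means to the full marker set (zeros for dropped)
    p_full = values.shape[1]
    loadings = np.zeros((p_full, want_pcs))
    loadings[keep] = pca_kept.loadings
    pca = PcaModel(loadings=loadings, eigenvalues=pca_kept.eigenvalues, means=means)

    T = centered @ loadings  # PC scores (n x r)
    grand = T.mean(axis=0)
    Sw = np.zeros((want_pcs, want_pcs))
    Sb = np.zeros((want_pcs, want_pcs))
    for g in range(K):
        Tg = T[inv == g]
        mg = Tg.mean(axis=0)
        Dg = Tg - mg
        Sw += Dg.T @ Dg
        dm = (mg - grand)[:, None]
        Sb += counts[g] * (dm @ dm.T)
    Sw /= max(n - K, 1)
    Sb /= n - 1
    Sw = Sw + _EPS_FRACTION * np.mean(np.diag(Sw) + 1e-300) * np.eye(want_pcs)

    d = min(K - 1, want_pcs) if n_das is None else min(n_das, K - 1, want_pcs)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:d]
    disc_eig = np.clip(evals[order], 0, None)
    axes = evecs[:, order]  # a^T Sw a = I normalization from eigh

    marker_loadings = loadings @ axes
    signs = _fix_signs(marker_loadings)
    axes = axes * signs
    marker_loadings = marker_loadings * signs

    scores = centered @ marker_loadings
    centroids = np.vstack([scores[inv == g].mean(axis=0) for g in range(K)])

    return DapcModel(
        pca=pca,
        n_retained_pcs=want_pcs,
        disc_axes=axes,
        disc_eigenvalues=disc_eig,
        scores=scores,
        marker_loadings=marker_loadings,
        groups=groups,
        labels=labels,
        centroids=centroids,
        within_cov=Sw,
        markers=markers,
        dropped_markers=dropped,
    )


def assignment_accuracy(
    model: DapcModel,
    X,
    labels,
    method: str = "resubstitution",
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Fraction of individuals reassigned to their true group.

    ``resubstitution`` (the conventional DAPC "reassignment accuracy")
    predicts the training individuals from the fitted model; ``cv`` runs a
    stratified cross-validation that refits the model per fold.
    """
    values, markers = _as_matrix(X)
    if model.markers is not None and markers is not None and markers != model.markers:
        raise ValueError("marker set of X does not match the fitted model")
    if values.shape[1] != model.marker_loadings.shape[0]:
        raise ValueError("marker set of X does not match the fitted model")
    labels = np.asarray(labels)

    if method == "resubstitution":
        return float(np.mean(model.predict(values) == labels))
    if method == "cv":
        from sklearn.model_selection import StratifiedKFold

        counts = np.bincount(np.unique(labels, return_inverse=True)[1])
        folds = min(n_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        correct = 0
        for train, test in skf.split(values, labels):
            sub = fit_dapc(values[train], labels[train], n_pcs=model.n_retained_pcs)
            correct += int(np.sum(sub.predict(values[test]) == labels[test]))
        return correct / len(labels)
    raise ValueError(f"unknown accuracy method {method!r}")


def axis_significance(
    model: DapcModel, labels=None, alpha: float = 0.05
) -> AxisSignificance:
    """Test the group effect on each discriminant axis.

    One-way linear model (axis score ~ group) F-test per axis, with
    Benjamini-Hochberg step-up across all retained axes; an axis is
    significant when q < ``alpha``.  Constant-score axes get p = 1 and a
    degenerate flag.
    """
    labels = model.labels if labels is None else np.asarray(labels)
    groups = np.unique(labels)
    n_axes = model.n_axes
    f_stat = np.full(n_axes, np.nan)
    p = np.ones(n_axes)
    degenerate = np.zeros(n_axes, dtype=bool)
    for a in range(n_axes):
        y = model.scores[:, a]
        if np.ptp(y) == 0:
            degenerate[a] = True
            continue
        samples = [y[labels == g] for g in groups]
        f_stat[a], p[a] = stats.f_oneway(*samples)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return AxisSignificance(
        f_statistic=f_stat,
        p_values=p,
        q_values=q,
        significant=q < alpha,
        degenerate=degenerate,
        alpha=alpha,
    )
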