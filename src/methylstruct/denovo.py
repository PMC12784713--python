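"""De novo methylation groups: K-means with BIC selection plus DAPC refit.

Instead of sampling sites, groups are inferred from the methylation data
itself: K-means on the retained principal components, with the number of
clusters chosen by the lowest BIC under the spherical-Gaussian profile form
``BIC = n ln(WSS/n) + k ln(n)``.  A PCA scree elbow is reported as advisory
metadata; when it disagrees with the BIC choice, BIC wins and the
disagreement is logged.  A second DAPC is then fitted with the de novo
labels (K-1 rule), and the number of reported discriminant components
defaults to the elbow of the discriminant-eigenvalue scree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .dapc import DapcModel, fit_dapc, fit_pca
from .transforms import HellingerMatrix, center_columns

__all__ = ["DeNovoGrouping", "kmeans_bic", "scree_elbow", "denovo_dapc"]

logger = logging.getLogger(__name__)


@dataclass
class DeNovoGrouping:
    k_candidates: np.ndarray
    bic: np.ndarray  # per candidate k
    selected_k: int  # argmin BIC, ties -> smaller k
    labels: np.ndarray  # individual -> group (0-based)
    scree_dimension: int  # advisory PCA scree elbow
    scree_no_elbow: bool
    seed: int
    n_starts: int
    dropped_k: list[int] = field(default_factory=list)


def kmeans_bic(
    pc_scores: np.ndarray,
    k_range=range(1, 9),
    n_starts: int = 50,
    seed: int = 0,
    eigenvalues: np.ndarray | None = None,
) -> DeNovoGrouping:
    """Best-of-``n_starts`` K-means per k, scored by BIC.

    WSS is the total within-cluster sum of squares over the retained PCs;
    ``BIC = n ln(WSS/n) + k ln(n)`` and the selected k minimizes it.  The
    k-means++ seeding stream is fixed by ``seed``, so results are
    bit-reproducible.
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range if 1 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no valid candidate")
    bics, labelings, dropped = [], [], []
    kept_ks = []
    for k in ks:
        if k == 1:
            center = X.mean(axis=0)
            wss = float(((X - center) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=n_starts, random_state=seed, tol=1e-6
            ).fit(X)
            lab = km.labels_
            wss = float(km.inertia_)
            if len(np.unique(lab)) < k:
                logger.warning("k=%d produced an empty cluster; dropped", k)
                dropped.append(k)
                continue
        bics.append(n * np.log(max(wss, 1e-300) / n) + k * np.log(n))
        labelings.append(lab)
        kept_ks.append(k)
    best = int(np.argmin(bics))  # first minimum -> smaller k on exact ties
    if eigenvalues is None:
        ev = np.var(X, axis=0, ddof=1)
        eigenvalues = np.sort(ev)[::-1]
    dim, no_elbow = scree_elbow(eigenvalues) if len(eigenvalues) >= 3 else (1, True)
    return DeNovoGrouping(
        k_candidates=np.asarray(kept_ks),
        bic=np.asarray(bics),
        selected_k=kept_ks[best],
        labels=labelings[best],
        scree_dimension=dim,
        scree_no_elbow=no_elbow,
        seed=seed,
        n_starts=n_starts,
        dropped_k=dropped,
    )


def scree_elbow(eigenvalues: np.ndarray) -> tuple[int, bool]:
    """Elbow of a scree curve by maximal perpendicular distance to the chord.

    The suggested dimension is the component just before the point farthest
    from the straight line joining the first and last scree values.  A
    collinear (monotone-flat) scree has no elbow: returns (1, True).
    """
    ev = np.asarray(eigenvalues, dtype=float)
    m = len(ev)
    if m < 3:
        raise ValueError("scree elbow needs at least 3 eigenvalues")
    x = np.arange(1, m + 1, dtype=float)
    # distance from each point to the chord (x1,y1)-(xm,ym)
    dx, dy = x[-1] - x[0], ev[-1] - ev[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (ev - ev[0])) / norm
    if dist.max() < 1e-12 * max(abs(ev[0]), 1.0):
        return 1, True
    elbow_point = int(np.argmax(dist)) + 1  # 1-based index of the kink
    return max(elbow_point - 1, 1), False


def denovo_dapc(
    X: HellingerMatrix | np.ndarray,
    grouping: DeNovoGrouping,
) -> tuple[DapcModel, int]:
    """DAPC refit on the de novo groups (K-1 retention).

    All K-1 discriminant axes are retained internally; the returned
    ``n_report`` is the discriminant-eigenvalue scree elbow, the number of
    components one would report/plot.
    """
    if grouping.selected_k < 2:
        raise ValueError("de novo DAPC needs k >= 2")
    model = fit_dapc(X, grouping.labels)
    if len(model.disc_eigenvalues) >= 3:
        n_report, no_elbow = scree_elbow(model.disc_eigenvalues)
        if no_elbow:
            n_report = model.n_axes
    else:
        n_report = model.n_axes
    return model, n_report
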