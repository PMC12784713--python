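"""Discriminant-marker selection and the minimal informative marker set.

Markers driving group structure are flagged by the Mahalanobis distance of
their discriminant-loading vectors from the bulk of markers (chi-square
p-values, Benjamini-Hochberg FDR < 5%).  Iterative DAPC refits on
progressively larger top-ranked subsets yield an accuracy-vs-subset-size
curve; a continuous piecewise-linear (segmented) regression with 1-25
breakpoints is fitted to that curve, the model with the lowest AIC is
selected, and the first breakpoint defines the minimal informative set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dapc import DapcModel, assignment_accuracy, axis_significance, fit_dapc
from .transforms import HellingerMatrix

__all__ = [
    "MarkerRanking",
    "AccuracyCurve",
    "SegmentedFit",
    "loading_mahalanobis",
    "mahalanobis_ranking",
    "default_grid",
    "accuracy_curve",
    "fit_piecewise",
    "segmented_minimal_set",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerRanking:
    """Per-marker Mahalanobis distances across retained discriminant axes."""

    markers: list[str] | None
    distances: np.ndarray  # squared Mahalanobis distance per marker
    p_values: np.ndarray  # chi-square upper tail, df = number of axes
    q_values: np.ndarray  # BH across markers
    order: np.ndarray  # marker indices by decreasing distance
    significant: np.ndarray  # q < alpha
    axes_used: np.ndarray  # discriminant-axis indices the distances span
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def top(self, k: int) -> np.ndarray:
        """Indices of the k top-ranked significant markers."""
        sig_ranked = self.order[self.significant[self.order]]
        return sig_ranked[:k]


@dataclass
class AccuracyCurve:
    sizes: np.ndarray  # strictly increasing subset sizes actually evaluated
    accuracy: np.ndarray  # assignment accuracy per size
    ranking: MarkerRanking
    degenerate_sizes: list[int] = field(default_factory=list)


@dataclass
class SegmentedFit:
    """Candidate segmented models (1..b_max breakpoints) and the AIC winner."""

    candidates: list[dict]  # per b: breakpoints, coefs, rss, aic
    selected: dict
    first_breakpoint: float
    minimal_size: int
    flat_break_warning: bool = False

    @property
    def aic_table(self) -> np.ndarray:
        return np.array([(c["n_breakpoints"], c["aic"]) for c in self.candidates])


def loading_mahalanobis(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Mahalanobis distance of each row from the bulk of rows.

    Classical (non-robust) mean and covariance across rows; p-values from
    the chi-square upper tail with df = number of columns.  A singular
    covariance is ridge-regularized with a logged warning.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    mu = L.mean(axis=0)
    D = L - mu
    if L.shape[1] == 1:
        d2 = D[:, 0] ** 2 / D.var(ddof=1)
    else:
        cov = np.cov(D, rowvar=False)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            logger.warning("singular loading covariance; using regularized inverse")
            cov_inv = np.linalg.inv(
                cov + 1e-10 * np.mean(np.diag(cov)) * np.eye(len(cov))
            )
        d2 = np.einsum("ij,jk,ik->i", D, cov_inv, D)
    d2 = np.clip(d2, 0, None)
    return d2, stats.chi2.sf(d2, df=L.shape[1])


def mahalanobis_ranking(
    model: DapcModel,
    axes: str | np.ndarray = "significant",
    alpha: float = 0.05,
) -> MarkerRanking:
    """Rank markers by Mahalanobis distance of their loading vectors.

    ``distance_j = (l_j - mu)^T Sigma^{-1} (l_j - mu)`` with ``mu``/``Sigma``
    the mean and covariance of loading vectors across markers; p-values from
    the chi-square upper tail with df = number of axes, BH-adjusted across
    markers.  ``axes`` selects which discriminant axes span the loading
    space: ``"significant"`` (group-effect q < 0.05; falls back to all axes
    if none is), ``"all"``, or an explicit index array.
    """
    if isinstance(axes, str):
        if axes == "all":
            idx = np.arange(model.n_axes)
        elif axes == "significant":
            sig = axis_significance(model, alpha=alpha).significant
            idx = np.flatnonzero(sig)
            if idx.size == 0:
                logger.warning("no significant discriminant axis; using all axes")
                idx = np.arange(model.n_axes)
        else:
            raise ValueError(f"unknown axes mode {axes!r}")
    else:
        idx = np.asarray(axes, dtype=int)

    d2, p = loading_mahalanobis(model.marker_loadings[:, idx])
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    order = np.argsort(-d2, kind="stable")
    return MarkerRanking(
        markers=model.markers,
        distances=d2,
        p_values=p,
        q_values=q,
        order=order,
        significant=q < alpha,
        axes_used=idx,
        alpha=alpha,
    )


def default_grid(
    n_markers: int, min_step: int = 10, target_points: int = 40
) -> list[int]:
    """Evenly spaced subset sizes from one step up to ``n_markers``.

    The step is ``max(min_step, ceil(n_markers / target_points))``, i.e. the
    grid is proportional to the significant-set size and never finer than
    ``min_step``.  Sampling below ~10 markers would let the segmented fit
    resolve the overfitting-driven curvature of the first few subset sizes
    (assignment accuracy rises with the retained-PC dimension alone there),
    which drags the first breakpoint below the scale on which the minimal
    set is interpreted.  For very small significant sets (< 4 points) the
    grid falls back to every rank.
    """
    step = max(min_step, -(-n_markers // target_points))
    sizes = list(range(step, n_markers + 1, step))
    if len(sizes) < 4:
        return list(range(1, n_markers + 1))
    if sizes[-1] != n_markers:
        sizes.append(n_markers)
    return sizes


def accuracy_curve(
    X: HellingerMatrix | np.ndarray,
    labels,
    ranking: MarkerRanking,
    grid: list[int] | None = None,
) -> AccuracyCurve:
    """Refit DAPC on progressively larger top-ranked significant-marker
    subsets (same K-1 retention rule) and record reassignment accuracy.

    Subsets whose markers are all zero-variance are recorded as degenerate
    and skipped.  Deterministic given inputs.
    """
    values = X.values if isinstance(X, HellingerMatrix) else np.asarray(X, dtype=float)
    n_sig = ranking.n_significant
    if n_sig < 1:
        raise ValueError("no significant markers to build an accuracy curve from")
    if grid is None:
        grid = default_grid(n_sig)
    grid = sorted(set(int(g) for g in grid))
    if grid[0] < 1 or grid[-1] > n_sig:
        raise ValueError(f"grid must lie within [1, {n_sig}]")

    sizes, accs, degenerate = [], [], []
    for k in grid:
        cols = ranking.top(k)
        sub = values[:, cols]
        try:
            model = fit_dapc(sub, labels)
        except ValueError:
            degenerate.append(k)
            continue
        accs.append(assignment_accuracy(model, sub, labels))
        sizes.append(k)
    return AccuracyCurve(
        sizes=np.asarray(sizes),
        accuracy=np.asarray(accs),
        ranking=ranking,
        degenerate_sizes=degenerate,
    )


# --- continuous piecewise-linear (segmented) least squares ---------------


def _design(x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in psi:
        cols.append(np.clip(x - b, 0, None))
    return np.column_stack(cols)


def fit_piecewise(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    """OLS fit of a continuous piecewise-linear model with fixed breakpoints.

    Returns ``(coefs, rss, fitted)``; coefs are intercept, base slope, and
    one slope change per breakpoint.
    """
    A = _design(x, np.sort(psi))
    coefs, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coefs
    rss = float(((y - fitted) ** 2).sum())
    return coefs, rss, fitted

def _muggeo(x, y, psi, max_iter=50, tol=1e-6):
    """Iterative-linearization breakpoint refinement (damped updates)."""
    lo, hi = x.min(), x.max()
    span = hi - lo
    psi = np.sort(np.asarray(psi, dtype=float))
    best = None
    for _ in range(max_iter):
        U = np.clip(x[:, None] - psi[None, :], 0, None)
        V = -(x[:, None] > psi[None, :]).astype(float)
        A = np.column_stack([np.ones_like(x), x, U, V])
        coefs, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        beta = coefs[2 : 2 + len(psi)]
        gamma = coefs[2 + len(psi) :]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(beta) > 1e-12, gamma / beta, 0.0)
        step = np.clip(step, -0.25 * span, 0.25 * span)
        new_psi = np.sort(np.clip(psi + step, lo + 1e-9 * span, hi - 1e-9 * span))
        _, rss, _ = fit_piecewise(x, y, new_psi)
        if best is None or rss < best[1] - 1e-15:
            best = (new_psi, rss)
        if np.max(np.abs(new_psi - psi)) < tol * span:
            psi = new_psi
            break
        psi = new_psi
    psi = best[0]
    coefs, rss, fitted = fit_piecewise(x, y, psi)
    return psi, coefs, rss


def _grid_candidates(x: np.ndarray) -> np.ndarray:
    xs = np.unique(x)
    return (xs[1:] + xs[:-1]) / 2.0  # midpoints, strictly inside the range


def _fit_b_breakpoints(x, y, b, rng):
    """Best continuous piecewise fit with exactly b breakpoints.

    Exhaustive midpoint grid search for b <= 2; Muggeo-style iteration from
    quantile-spaced (and jittered) starts, 10 restarts, otherwise.
    """
    cand = _grid_candidates(x)
    if b <= 2 and len(cand) >= b:
        best = None
        if b == 1:
            combos = (np.array([c]) for c in cand)
        else:
            combos = (
                np.array([cand[i], cand[j]])
                for i in range(len(cand) - 1)
                for j in range(i + 1, len(cand))
            )
        for psi in combos:
            coefs, rss, _ = fit_piecewise(x, y, psi)
            if best is None or rss < best[2]:
                best = (psi, coefs, rss)
        psi, coefs, rss = best
        # polish the grid optimum
        psi2, coefs2, rss2 = _muggeo(x, y, psi)
        if rss2 < rss:
            psi, coefs, rss = psi2, coefs2, rss2
        return psi, coefs, rss

    lo, hi = x.min(), x.max()
    quantile_start = np.quantile(x, np.linspace(0, 1, b + 2)[1:-1])
    best = None
    for r in range(10):
        start = quantile_start.copy()
        if r > 0:
            start = start + rng.normal(0, 0.05 * (hi - lo), size=b)
            start = np.clip(start, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo))
        psi, coefs, rss = _muggeo(x, y, start)
        if best is None or rss < best[2]:
            best = (psi, coefs, rss)
    return best


def segmented_minimal_set(
    curve: AccuracyCurve,
    max_breakpoints: int = 25,
    seed: int = 0,
) -> tuple[SegmentedFit, np.ndarray]:
    """Select the AIC-best segmented model and derive the minimal marker set.

    Models with 1..``max_breakpoints`` breakpoints are fitted to the
    accuracy curve (the cap is lowered to floor((n_points - 2) / 2) so every
    segment keeps >= 2 points).  ``AIC = n ln(RSS/n) + 2 (2 + 2b)`` counts
    intercept, base slope, and one slope-change plus one location per
    breakpoint.  The minimal set is the top-ranked markers up to the first
    breakpoint of the winning model, rounded up to the nearest evaluated
    grid size.

    Returns the fit and the marker indices of the minimal set.
    """
    x = np.asarray(curve.sizes, dtype=float)
    y = np.asarray(curve.accuracy, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 curve points to identify a breakpoint")
    b_max = min(max_breakpoints, (n - 2) // 2)
    rng = np.random.default_rng(seed)

    candidates = []
    for b in range(1, b_max + 1):
        psi, coefs, rss = _fit_b_breakpoints(x, y, b, rng)
        n_params = 2 + 2 * b
        aic = n * np.log(max(rss, 1e-12) / n) + 2 * n_params
        candidates.append(
            {
                "n_breakpoints": b,
                "breakpoints": np.sort(psi),
                "coefs": coefs,
                "rss": rss,
                "aic": float(aic),
            }
        )
    selected = min(candidates, key=lambda c: c["aic"])
    first_bp = float(selected["breakpoints"][0])

    # flat-break warning: negligible slope change at the first breakpoint
    slope_changes = selected["coefs"][2:]
    scale = max(abs(selected["coefs"][1]), np.max(np.abs(slope_changes)), 1e-12)
    flat = abs(slope_changes[0]) < 0.01 * scale
    if flat:
        logger.warning("first breakpoint has a near-zero slope change")

    at_least = curve.sizes[curve.sizes >= np.ceil(first_bp)]  # conservative: round up
    minimal_size = int(at_least[0]) if at_least.size else int(curve.sizes[-1])
    minimal = curve.ranking.top(minimal_size)
    fit = SegmentedFit(
        candidates=candidates,
        selected=selected,
        first_breakpoint=first_bp,
        minimal_size=minimal_size,
        flat_break_warning=bool(flat),
    )
    return fit, minimal


def plot_accuracy_curve(curve: AccuracyCurve, fit: SegmentedFit | None, path) -> None:
    """Accuracy-vs-subset-size curve with the fitted segments (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.sizes, curve.accuracy, "o-", ms=3, label="reassignment accuracy")
    if fit is not None:
        x = np.linspace(curve.sizes.min(), curve.sizes.max(), 400)
        _, _, fitted = fit_piecewise(
            np.asarray(curve.sizes, float), curve.accuracy, fit.selected["breakpoints"]
        )
        ax.plot(curve.sizes, fitted, "-", color="C3", label="segmented fit")
        ax.axvline(fit.first_breakpoint, ls="--", color="C3", alpha=0.6)
        ax.annotate(
            f"first breakpoint = {fit.first_breakpoint:.0f}",
            (fit.first_breakpoint, curve.accuracy.min()),
            textcoords="offset points",
            xytext=(5, 5),
            fontsize=8,
        )
    ax.set_xlabel("top-ranked markers")
    ax.set_ylabel("assignment accuracy")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
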