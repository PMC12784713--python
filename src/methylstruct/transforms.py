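"""Hellinger transformation and column centering applied before ordination.

The Hellinger transform maps each individual's methylation profile to the
square root of its row-relative values.  Euclidean distance between
transformed rows then equals the Hellinger distance between the raw
relative profiles, which avoids the "Euclidean paradox" of treating
individuals sharing no methylated markers as similar to individuals that
share markers but differ in level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RpmMatrix

__all__ = ["HellingerMatrix", "hellinger", "center_columns"]


@dataclass
class HellingerMatrix:
    """Square-rooted row-relative methylation levels; values in [0, 1].

    Each row with a positive total has squared values summing to 1.
    """

    individuals: list[str]
    markers: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def hellinger(rpm: RpmMatrix) -> HellingerMatrix:
    """value(i, j) = sqrt( rpm(i, j) / sum_j rpm(i, j) ).

    Raises ``ValueError`` naming the individual for an all-zero row, which
    cannot be relativized.
    """
    totals = rpm.values.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(
            f"individual {rpm.individuals[bad]!r} has an all-zero methylation "
            "profile and cannot be Hellinger-transformed"
        )
    values = np.sqrt(rpm.values / totals[:, None])
    return HellingerMatrix(
        individuals=list(rpm.individuals), markers=list(rpm.markers), values=values
    )


def center_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column at zero mean.

    Returns ``(centered, means, zero_variance_mask)``; the means allow
    projecting new data, the mask flags constant columns (which carry no
    discriminant information and are dropped before PCA by callers).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("centering requires at least 2 rows")
    means = X.mean(axis=0)
    centered = X - means
    zero_var = np.ptp(X, axis=0) == 0
    return centered, means, zero_var
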