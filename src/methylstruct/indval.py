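"""Indicator values and characteristic hypermethylated markers.

The Dufrene-Legendre indicator value combines specificity A (the share of a
marker's mean abundance concentrated in one group) and fidelity B (the
fraction of the group's sampling units where the marker is present):
``IndVal = A x B x 100``.  To avoid circular significance testing, a marker
is called characteristic of the groups whose IndVal falls in the upper
class of a one-break Jenks natural-breaks classification of its IndVal
values across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndValTable",
    "indval",
    "jenks_one_break",
    "characteristic_markers",
]

logger = logging.getLogger(__name__)


@dataclass
class IndValTable:
    markers: list
    groups: list
    A: np.ndarray  # specificity, markers x groups, rows sum to 1
    B: np.ndarray  # fidelity (presence fraction), markers x groups
    indval: np.ndarray  # A * B * 100, percent scale
    breaks: np.ndarray | None = None  # per-marker Jenks break value (NaN if none)
    characteristic: np.ndarray | None = None  # markers x groups bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.indval, index=self.markers, columns=self.groups)


def indval(values: np.ndarray, unit_group_labels, markers=None, groups=None) -> IndValTable:
    """IndVal scores per marker x group on an abundance matrix (raw RPM).

    ``A(j, g)`` = mean abundance of marker j in group g divided by the sum
    of its group means; ``B(j, g)`` = fraction of group-g units with
    abundance > 0.  A marker with all-zero group means scores 0 everywhere.
    The sampling unit is whatever the rows are — individuals by default in
    this pipeline.
    """
    X = np.asarray(getattr(values, "values", values), dtype=float)
    labels = np.asarray(unit_group_labels)
    uniq = sorted(set(labels.tolist())) if groups is None else list(groups)
    if len(uniq) < 2:
        raise ValueError("IndVal requires at least 2 groups")
    masks = [labels == g for g in uniq]
    if any(m.sum() == 0 for m in masks):
        empty = uniq[[m.sum() for m in masks].index(0)]
        raise ValueError(f"group {empty!r} has no sampling units")

    means = np.vstack([X[m].mean(axis=0) for m in masks]).T  # markers x groups
    B = np.vstack([(X[m] > 0).mean(axis=0) for m in masks]).T
    totals = means.sum(axis=1)
    A = np.zeros_like(means)
    nz = totals > 0
    A[nz] = means[nz] / totals[nz, None]
    iv = A * B * 100.0
    if markers is None:
        markers = list(getattr(values, "markers", range(X.shape[1])))
    return IndValTable(markers=list(markers), groups=uniq, A=A, B=B, indval=iv)


def jenks_one_break(values) -> tuple[float, np.ndarray]:
    """Optimal one-break (two-class) Jenks natural-breaks classification.

    Exhausts all n-1 ordered split positions and returns the one minimizing
    the total within-class sum of squared deviations; ties go to the split
    with the smaller upper class.  The break value is the midpoint between
    the two boundary values.  Returns ``(break_value, upper_class_mask)``
    over the input order; raises for all-equal input (no break exists).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; no break exists")
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = len(s)
    # prefix sums give each candidate split's within-class SSE in O(n)
    c1 = np.cumsum(s)
    c2 = np.cumsum(s**2)
    idx = np.arange(1, n)  # split after position idx-1 (lower class size idx)
    sse_lo = c2[idx - 1] - c1[idx - 1] ** 2 / idx
    hi_n = n - idx
    hi_sum = c1[-1] - c1[idx - 1]
    hi_sq = c2[-1] - c2[idx - 1]
    sse_hi = hi_sq - hi_sum**2 / hi_n
    total = sse_lo + sse_hi
    # ties -> larger split index -> smaller upper class
    best = int(np.max(np.flatnonzero(total == total.min())))
    split = int(idx[best])
    brk = (s[split - 1] + s[split]) / 2.0
    upper = np.zeros(n, dtype=bool)
    upper[order[split:]] = True
    return float(brk), upper


def characteristic_markers(table: IndValTable) -> IndValTable:
    """Flag, per marker, the groups whose IndVal lies above its Jenks break.

    Markers whose IndVal values are identical across groups (including
    all-zero markers) are characteristic of no group.  Fills the ``breaks``
    and ``characteristic`` fields and returns the same table.
    """
    m, g = table.indval.shape
    breaks = np.full(m, np.nan)
    flags = np.zeros((m, g), dtype=bool)
    n_degenerate = 0
    for j in range(m):
        row = table.indval[j]
        if np.ptp(row) == 0:
            n_degenerate += 1
            continue
        brk, upper = jenks_one_break(row)
        breaks[j] = brk
        flags[j] = upper
    if n_degenerate:
        logger.info("%d markers with uniform IndVal are characteristic of no group", n_degenerate)
    table.breaks = breaks
    table.characteristic = flags
    return table
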