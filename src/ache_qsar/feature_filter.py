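"""Greedy pairwise-correlation pruning of collinear descriptors.

The rule is the mean-absolute-correlation greedy elimination popularized by
caret's ``findCorrelation``: while any descriptor pair has |r| strictly above
the cutoff, take the worst pair and drop whichever member is on average more
correlated with everything else still in play.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorMatrix


@dataclass
class FilterReport:
    """Outcome of the pruning: kept keys, dropped (key, partner, r), constants."""

    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    zero_variance_dropped: list[str] = field(default_factory=list)

    @property
    def dropped_keys(self) -> list[str]:
        return [d[0] for d in self.dropped]


def drop_zero_variance(X: np.ndarray, col_ids: list[str] | None = None):
    """Remove constant columns; returns the reduced matrix and dropped keys."""
    X = np.asarray(X, dtype=float)
    if col_ids is None:
        col_ids = [str(i) for i in range(X.shape[1])]
    keep = np.array([len(np.unique(X[:, j])) > 1 for j in range(X.shape[1])])
    if not keep.any():
        raise ValueError("all columns have zero variance")
    dropped = [c for c, k in zip(col_ids, keep) if not k]
    return X[:, keep], [c for c, k in zip(col_ids, keep) if k], dropped


def pearson_matrix(X: np.ndarray, col_ids: list[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix of the columns of X.

    Zero-variance columns must be removed beforehand; one present raises an
    error naming the column.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = col_ids[bad[0]] if col_ids else str(bad[0])
        raise ValueError(f"zero-variance column present: {name}")
    R = np.corrcoef(X, rowvar=False)
    # round away last-bit noise so strict cutoff comparisons are stable
    # (a hand-exact r of 3/5 must not float to 0.6000000000000001)
    return np.clip(np.round(R, 12), -1.0, 1.0)


def drop_correlated(
    X: np.ndarray | DescriptorMatrix,
    cutoff: float = 0.7,
    col_ids: list[str] | None = None,
) -> FilterReport:
    """Greedy correlation filter at the given cutoff (strictly-greater test).

    At each step the pair with the largest |r| > cutoff is found; the member
    with the larger mean absolute correlation against all remaining columns is
    dropped (ties drop the later column).  Terminates when no pair exceeds the
    cutoff.  Constant columns are removed first and reported separately.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if isinstance(X, DescriptorMatrix):
        col_ids = list(X.col_ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    if col_ids is None:
        col_ids = [str(i) for i in range(X.shape[1])]

    Xv, keys, zero_var = drop_zero_variance(X, col_ids)
    R = np.abs(pearson_matrix(Xv, keys))
    np.fill_diagonal(R, 0.0)

    active = list(range(len(keys)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = R[np.ix_(active, active)]
        i_flat = np.argmax(sub)
        a, b = divmod(i_flat, len(active))
        if a > b:  # keep first occurrence deterministic (row-major argmax)
            a, b = b, a
        r_max = sub[a, b]
        if not r_max > cutoff:
            break
        mean_a = sub[a].mean()
        mean_b = sub[b].mean()
        # drop the member with the larger mean |r|; ties drop the later column
        victim, partner = (a, b) if mean_a > mean_b else (b, a)
        vi, pi = active[victim], active[partner]
        dropped.append((keys[vi], keys[pi], float(R[vi, pi])))
        active.remove(vi)
    kept = [keys[i] for i in active]
    return FilterReport(kept=kept, dropped=dropped, zero_variance_dropped=zero_var)


def apply_filter(X: DescriptorMatrix, report: FilterReport) -> DescriptorMatrix:
    """Project a descriptor matrix onto the kept columns of a filter report."""
    idx = [X.col_ids.index(k) for k in report.kept]
    return DescriptorMatrix(
        values=X.values[:, idx],
        row_ids=list(X.row_ids),
        col_ids=list(report.kept),
        family=X.family,
        mode=X.mode,
    )


def max_offdiag_correlation(X: np.ndarray) -> float:
    """Largest off-diagonal |r| among the columns of X (post-filter audit)."""
    R = np.abs(pearson_matrix(np.asarray(X, dtype=float)))
    np.fill_diagonal(R, 0.0)
    return float(R.max()) if R.size else 0.0
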