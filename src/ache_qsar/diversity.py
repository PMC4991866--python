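"""Kennard-Stone maximin selection of representative, diverse compound subsets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class DiversitySelection:
    """An ordered diversity pick with its descriptor-space provenance."""

    selected_ids: list[str]
    selected_indices: list[int]
    k: int
    metric: str
    space: str
    min_pairwise_distance: float
    median_pairwise_distance: float


def kennard_stone(X: np.ndarray, k: int, metric: str = "euclidean") -> list[int]:
    """Kennard-Stone maximin ordering: k row indices spanning the space.

    The first two picks are the most distant pair; each later pick maximizes
    its minimum distance to the already-selected set.  Ties break to the
    lowest row index, making the selection deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot select k={k} from n={n} points")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    D = cdist(X, X, metric=metric)
    # diameter pair; ties resolve to the lexicographically smallest (i, j)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    first, second = (i, j) if i < j else (j, i)
    selected = [int(first), int(second)]
    min_dist = np.minimum(D[first], D[second])
    min_dist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return selected


def select_diversity_set(
    compounds: pd.DataFrame,
    X: np.ndarray,
    k: int = 30,
    active_only: bool = True,
    metric: str = "euclidean",
    space: str = "",
) -> DiversitySelection:
    """Pick k diverse compounds, by default restricted to the actives.

    ``compounds`` must carry ``compound_id`` and ``activity_class`` columns
    row-aligned with ``X``.  Returns the ordered ids plus a coverage summary
    (min / median pairwise distance within the selection).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(compounds) != X.shape[0]:
        raise ValueError("compounds and X are not row-aligned")
    if active_only:
        mask = (compounds["activity_class"] == "active").to_numpy()
        n_act = int(mask.sum())
        if n_act < k:
            raise ValueError(f"only {n_act} active compounds available, need k={k}")
    else:
        mask = np.ones(len(compounds), dtype=bool)
    sub_idx = np.flatnonzero(mask)
    picks_local = kennard_stone(X[sub_idx], k, metric=metric)
    picks = [int(sub_idx[i]) for i in picks_local]
    ids = [str(compounds["compound_id"].iloc[i]) for i in picks]
    D = cdist(X[picks], X[picks], metric=metric)
    upper = D[np.triu_indices(k, 1)]
    return DiversitySelection(
        selected_ids=ids,
        selected_indices=picks,
        k=k,
        metric=metric,
        space=space,
        min_pairwise_distance=float(upper.min()),
        median_pairwise_distance=float(np.median(upper)),
    )
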