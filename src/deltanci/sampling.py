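"""SPXY and Kennard–Stone train/test partitioning.

SPXY (sample set partitioning based on joint X–Y distance) extends
Kennard–Stone max–min selection to a joint metric

    d_xy(p, q) = d_x(p, q) / max d_x  +  d_y(p, q) / max d_y,

with Euclidean distance on the normalized descriptor block and absolute
difference on the normalized response, so the training set spans both the
descriptor space and the response range. Kennard–Stone is the X-only special
case (the response term drops out).

The greedy selection is deterministic: seed with the mutually farthest pair,
then repeatedly add the candidate whose minimum joint distance to the
selected set is largest; ties break toward the lowest row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dataio import Dataset, fit_normalization


class DegenerateDataError(ValueError):
    """All samples identical in both X and y: no distance structure."""


@dataclass
class SplitResult:
    """Outcome of a train/test partition."""

    train_ids: list[str]
    test_ids: list[str]
    selection_order: list[str]

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def joint_distance_matrix(
    X: np.ndarray, y: np.ndarray | None
) -> np.ndarray:
    """Symmetric joint X–Y distance matrix on normalized data.

    Each block is scaled by its own maximum, so entries lie in [0, 2]. A
    degenerate block (zero maximum distance, e.g. a constant response)
    contributes 0 rather than dividing by zero; if both blocks are
    degenerate the data carry no distance information and a
    :class:`DegenerateDataError` is raised. Pass ``y=None`` for the plain
    Kennard–Stone (X-only) metric.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    dx = squareform(pdist(X, metric="euclidean"))
    max_dx = dx.max()
    if y is None:
        if max_dx == 0.0:
            raise DegenerateDataError("all samples identical in X")
        return dx / max_dx
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise ValueError("X and y sample counts differ")
    dy = np.abs(y[:, None] - y[None, :])
    max_dy = dy.max()
    if max_dx == 0.0 and max_dy == 0.0:
        raise DegenerateDataError("all samples identical in both X and y")
    d = np.zeros((n, n))
    if max_dx > 0.0:
        d += dx / max_dx
    if max_dy > 0.0:
        d += dy / max_dy
    return d


def _greedy_maxmin(d: np.ndarray, n_train: int) -> list[int]:
    """Greedy max–min selection on a distance matrix; lowest index wins ties."""
    n = d.shape[0]
    # seed: the mutually farthest pair; np.argmax on the flattened matrix
    # returns the lowest (row, col) in row-major order among ties
    p, q = np.unravel_index(np.argmax(d), d.shape)
    if p > q:
        p, q = q, p
    selected = [int(p), int(q)]
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_train:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        best = int(np.argmax(min_d))  # first max among ties -> lowest index
        selected.append(remaining.pop(best))
    return selected


def spxy_split(
    data: Dataset, n_train: int, *, use_response: bool = True
) -> SplitResult:
    """Partition ``data`` into train/test by SPXY greedy max–min selection.

    Descriptors and response are normalized to [-1, 1] internally using the
    full set (the split precedes any screening, so all available descriptors
    participate in d_x). With ``use_response=False`` this is classic
    Kennard–Stone on X alone.
    """
    n = len(data)
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train={n_train} out of range [2, {n}]")
    nmap = fit_normalization(data, include_target=use_response)
    Xn = nmap.transform_matrix(data.X, data.descriptor_names)
    yn = nmap.apply_target(data.y) if use_response else None
    d = joint_distance_matrix(Xn, yn)
    order = _greedy_maxmin(d, n_train)
    ids = data.ids
    train_set = set(order)
    return SplitResult(
        train_ids=[ids[i] for i in sorted(order)],
        test_ids=[ids[i] for i in range(n) if i not in train_set],
        selection_order=[ids[i] for i in order],
    )


def kennard_stone_split(data: Dataset, n_train: int) -> SplitResult:
    """Classic Kennard–Stone partition (descriptor distances only)."""
    return spxy_split(data, n_train, use_response=False)


def train_size(n: int, fraction: float = 91.0 / 121.0) -> int:
    """Round-to-nearest training-set size for a given fraction (default the
    91-of-121 division used for the NCI benchmark sets)."""
    return int(round(fraction * n))
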