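"""PLS-based descriptor screening and GRNN input-subset selection.

Descriptors are ranked by the magnitude of their partial-least-squares
regression coefficients (computed on centered, [-1, 1]-scaled variables so
magnitudes are comparable across descriptors). The top-k shortlist (default
10) then feeds an exhaustive cross-validated subset search: every subset of
the shortlist that contains the primary descriptor (the DFT interaction
energy) is scored by K-fold CV RMSE of a GRNN with its smoothing factor
optimized per candidate, and the lowest-RMSE subset wins.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .dataio import PRIMARY_DESCRIPTOR, Dataset
from .grnn import CVConfig, DEFAULT_SIGMA_GRID, cv_predict, sigma_grid_values

logger = logging.getLogger(__name__)


class DegenerateResponseError(ValueError):
    """The response has zero variance; PLS directions are undefined."""


@dataclass
class PLSModel:
    """Fitted PLS regression on normalized variables."""

    n_components: int
    descriptor_names: list[str]
    x_center: np.ndarray
    y_center: float
    x_weights: np.ndarray    # (d, n_components)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray  # (d,) regression vector on centered variables

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_center) @ self.coefficients + self.y_center


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    descriptor_names: list[str] | None = None,
) -> PLSModel:
    """Fit a NIPALS PLS regression (deterministic, no random start).

    ``X`` and ``y`` are expected already scaled to [-1, 1]; centering is
    internal. With ``n_components`` equal to the rank of X the fit
    reproduces ordinary least squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if not 1 <= n_components <= min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} outside [1, {min(n - 1, d)}]"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateResponseError("response has zero variance")
    names = descriptor_names or [f"x{j}" for j in range(d)]
    if len(names) != d:
        raise ValueError("descriptor_names length mismatch")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = np.asarray(pls.coef_, dtype=float).reshape(-1)
    return PLSModel(
        n_components=n_components,
        descriptor_names=list(names),
        x_center=X.mean(axis=0),
        y_center=float(y.mean()),
        x_weights=np.asarray(pls.x_weights_),
        x_loadings=np.asarray(pls.x_loadings_),
        y_loadings=np.asarray(pls.y_loadings_),
        coefficients=coef,
    )


@dataclass
class ScreeningResult:
    """Descriptor ranking, shortlist and (after selection) the final subset."""

    ranking: list[tuple[str, float]]      # sorted by |coefficient| desc
    shortlist: list[str]
    final_subset: list[str] = field(default_factory=list)
    subset_scores: list[tuple[tuple[str, ...], float, float]] = field(
        default_factory=list
    )  # (subset, sigma, CV RMSE kcal/mol)


def rank_descriptors(model: PLSModel, k: int = 10) -> ScreeningResult:
    """Rank descriptors by |PLS coefficient|; shortlist the top ``k``.

    Ties keep the input column order (stable sort). ``k`` larger than the
    descriptor count is clamped with a warning.
    """
    d = len(model.descriptor_names)
    if k > d:
        logger.warning("k=%d exceeds %d descriptors; clamping", k, d)
        k = d
    order = np.argsort(-np.abs(model.coefficients), kind="stable")
    ranking = [
        (model.descriptor_names[j], float(model.coefficients[j]))
        for j in order
    ]
    return ScreeningResult(
        ranking=ranking,
        shortlist=[name for name, _ in ranking[:k]],
    )


def _candidate_subsets(
    shortlist: list[str], max_size: int
) -> list[tuple[str, ...]]:
    """All shortlist subsets containing the primary descriptor, ordered by
    (size, lexicographic names) so the first strict minimum wins ties."""
    others = sorted(n for n in shortlist if n != PRIMARY_DESCRIPTOR)
    out: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(others, size - 1):
            out.append(tuple(sorted((PRIMARY_DESCRIPTOR, *combo))))
    return out


def select_final_subset(
    screening: ScreeningResult,
    train: Dataset,
    cv: CVConfig,
    sigma_grid: tuple[float, float, float] = DEFAULT_SIGMA_GRID,
    max_size: int = 6,
) -> ScreeningResult:
    """Exhaustive CV-scored search for the GRNN input subset.

    Every candidate contains the primary descriptor; each is scored by the
    best (over the sigma grid) K-fold CV RMSE. The baseline single-descriptor
    subset is always in the pool, so the winner never scores worse than the
    raw-DFT-only model. Ties break toward the smaller subset, then
    lexicographic names; exact sigma ties toward the larger (smoother) sigma.
    """
    if PRIMARY_DESCRIPTOR not in screening.shortlist:
        raise ValueError(
            f"shortlist must contain {PRIMARY_DESCRIPTOR!r}"
        )
    sigmas = sigma_grid_values(sigma_grid)
    y = train.y[:, None]
    scores: list[tuple[tuple[str, ...], float, float]] = []
    best_subset: tuple[str, ...] | None = None
    best_rmse = np.inf
    best_sigma = float(sigmas[-1])
    for subset in _candidate_subsets(screening.shortlist, max_size):
        oof = cv_predict(train, list(subset), sigmas, cv)
        rmses = np.sqrt(np.mean((oof - y) ** 2, axis=0))
        pos = sigmas.size - 1 - int(np.argmin(rmses[::-1]))
        rmse = float(rmses[pos])
        scores.append((subset, float(sigmas[pos]), rmse))
        if rmse < best_rmse:
            best_subset, best_rmse, best_sigma = subset, rmse, float(sigmas[pos])
    assert best_subset is not None
    screening.final_subset = list(best_subset)
    screening.subset_scores = scores
    logger.info(
        "selected subset %s (sigma=%.2f, CV RMSE=%.4f kcal/mol) "
        "out of %d candidates",
        best_subset, best_sigma, best_rmse, len(scores),
    )
    return screening
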