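"""General regression neural network (GRNN) and the training pipeline.

The GRNN is lazy Gaussian-kernel regression (Nadaraya–Watson): every
training sample becomes a pattern neuron, and a query X is scored as

    y(X) = sum_i y_i exp(-||X - X_i||^2 / (2 sigma^2))
           / sum_i exp(-||X - X_i||^2 / (2 sigma^2)),

a convex combination of the training targets. The single tunable parameter
is the smoothing factor sigma: sigma -> 0 interpolates the training targets,
sigma -> infinity returns their mean. sigma is chosen by K-fold
cross-validation over a grid (default [0.1, 2] in steps of 0.1, on
descriptors scaled to [-1, 1]).

Applied to non-covalent interaction (NCI) energies, the network maps a small
set of descriptors — dominated by the cheap DFT interaction energy itself —
onto benchmark-quality reference energies, so the difference between the
GRNN output and the raw DFT value acts as a learned correction term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataio import (
    PRIMARY_DESCRIPTOR,
    TARGET_KEY,
    Dataset,
    NormalizationMap,
    SchemaError,
    fit_normalization,
)

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID = (0.1, 2.0, 0.1)
#: Fallback smoothing factor when no reference data are available to
#: optimize it (the shipped optimum for small-basis DFT descriptor sets).
DEFAULT_SIGMA = 0.2


class EmptyModelError(ValueError):
    """Prediction requested from a model with no pattern neurons."""


@dataclass
class CVConfig:
    """K-fold cross-validation settings (seeded shuffle, round-robin folds)."""

    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"K must be >= 2, got {self.k}")


@dataclass
class GRNNModel:
    """Stored (normalized) training patterns, targets and smoothing factor."""

    descriptor_names: list[str]
    patterns: np.ndarray      # (n, d) normalized training inputs
    targets: np.ndarray       # (n,) normalized training responses
    sigma: float
    normalization: NormalizationMap
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.patterns.shape[0] != self.targets.shape[0]:
            raise ValueError("patterns and targets disagree on sample count")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.descriptor_names:
            raise ValueError("descriptor_names must be nonempty")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


def _kernel_regress(
    sq_dist: np.ndarray, targets: np.ndarray, sigma: float
) -> np.ndarray:
    """Nadaraya–Watson estimate from squared distances, one row per query.

    The maximum exponent is shifted out before exponentiating, so the
    denominator is always >= 1 and distant queries degrade gracefully to
    the nearest pattern's target instead of 0/0.
    """
    expo = -sq_dist / (2.0 * sigma * sigma)
    shift = expo.max(axis=1, keepdims=True)
    w = np.exp(expo - shift)
    return (w @ targets) / w.sum(axis=1)


def _query_matrix(model: GRNNModel, query) -> np.ndarray:
    """Normalize a query (record dict, Dataset, or raw mapping/matrix)."""
    names = model.descriptor_names
    if isinstance(query, Dataset):
        missing = [n for n in names if n not in query.descriptor_names]
        if missing:
            raise SchemaError(f"query lacks descriptors {missing}")
        raw = np.column_stack([query.column(n) for n in names])
    elif isinstance(query, dict):
        missing = [n for n in names if n not in query]
        if missing:
            raise SchemaError(f"query lacks descriptors {missing}")
        raw = np.asarray([[float(query[n]) for n in names]])
    else:
        raw = np.atleast_2d(np.asarray(query, dtype=float))
        if raw.shape[1] != len(names):
            raise SchemaError(
                f"query has {raw.shape[1]} columns, model expects "
                f"{len(names)}"
            )
    return model.normalization.transform_matrix(raw, names)


def grnn_predict(
    model: GRNNModel, query, *, denormalize: bool = False
) -> np.ndarray:
    """Predict the (normalized) response for one or more queries.

    With ``denormalize=True`` the output is mapped back to kcal/mol via the
    model's stored normalization.
    """
    if model.n_patterns == 0:
        raise EmptyModelError("model has no pattern neurons")
    Q = _query_matrix(model, query)
    sq = cdist(Q, model.patterns, metric="sqeuclidean")
    out = _kernel_regress(sq, model.targets, model.sigma)
    if denormalize:
        out = model.normalization.invert_target(out)
    return out


def grnn_fit(
    train: Dataset,
    subset: list[str],
    sigma: float,
    normalization: NormalizationMap | None = None,
    training_meta: dict | None = None,
) -> GRNNModel:
    """Store the training set as pattern neurons (no iterative optimization).

    The number of pattern neurons equals the number of training samples.
    ``normalization`` defaults to a map fitted on ``train`` itself.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    missing = [n for n in subset if n not in train.descriptor_names]
    if missing:
        raise SchemaError(f"training set lacks descriptors {missing}")
    nmap = normalization or fit_normalization(train, include_target=True)
    raw = np.column_stack([train.column(n) for n in subset])
    patterns = nmap.transform_matrix(raw, subset)
    targets = np.asarray(nmap.apply_target(train.y), dtype=float)
    return GRNNModel(
        descriptor_names=list(subset),
        patterns=patterns,
        targets=targets,
        sigma=float(sigma),
        normalization=nmap,
        training_meta=training_meta or {},
    )


def kfold_partition(ids: list[str], cv: CVConfig) -> list[list[str]]:
    """Seeded shuffle then round-robin assignment into K folds.

    Fold sizes differ by at most one; the same seed always yields the same
    folds.
    """
    n = len(ids)
    if cv.k > n:
        raise ValueError(f"K={cv.k} exceeds sample count {n}")
    rng = np.random.default_rng(cv.seed)
    perm = rng.permutation(n)
    folds: list[list[str]] = [[] for _ in range(cv.k)]
    for pos, idx in enumerate(perm):
        folds[pos % cv.k].append(ids[idx])
    return folds


def _subset_matrix(data: Dataset, subset: list[str]) -> np.ndarray:
    return np.column_stack([data.column(n) for n in subset])


def cv_predict(
    train: Dataset,
    subset: list[str],
    sigmas: np.ndarray,
    cv: CVConfig,
) -> np.ndarray:
    """Out-of-fold predictions (kcal/mol) for every sigma on a grid.

    For each fold, the normalization map is refitted on the other K-1 folds
    only (no leakage), the held-out fold is predicted, and predictions are
    denormalized with that fold's map. Returns an (n, n_sigma) array aligned
    with the row order of ``train``.
    """
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if np.any(sigmas <= 0):
        raise ValueError("all sigma values must be > 0")
    ids = train.ids
    index = {i: pos for pos, i in enumerate(ids)}
    folds = kfold_partition(ids, cv)
    raw_X = _subset_matrix(train, subset)
    raw_y = train.y
    oof = np.empty((len(ids), sigmas.size))
    for fold in folds:
        val_idx = np.asarray([index[i] for i in fold])
        fit_mask = np.ones(len(ids), dtype=bool)
        fit_mask[val_idx] = False
        fit_X, fit_y = raw_X[fit_mask], raw_y[fit_mask]
        # per-fold [-1, 1] normalization of the subset columns and target
        ranges = {}
        for j, name in enumerate(subset):
            ranges[name] = (float(fit_X[:, j].min()),
                            float(fit_X[:, j].max()))
        ranges[TARGET_KEY] = (float(fit_y.min()), float(fit_y.max()))
        nmap = NormalizationMap(
            ranges,
            [n for n, (lo, hi) in ranges.items() if lo == hi],
        )
        P = nmap.transform_matrix(fit_X, subset)
        t = np.asarray(nmap.apply_target(fit_y), dtype=float)
        Q = nmap.transform_matrix(raw_X[val_idx], subset)
        sq = cdist(Q, P, metric="sqeuclidean")
        for s, sigma in enumerate(sigmas):
            pred_n = _kernel_regress(sq, t, sigma)
            oof[val_idx, s] = nmap.invert_target(pred_n)
    return oof


def cv_rmse(
    train: Dataset,
    subset: list[str],
    sigma: float,
    cv: CVConfig,
    *,
    return_oof: bool = False,
):
    """K-fold cross-validated RMSE (kcal/mol) of a GRNN at one sigma.

    With ``return_oof=True`` also returns the per-sample out-of-fold
    predictions (used for the cross-validated q^2).
    """
    oof = cv_predict(train, subset, np.asarray([sigma]), cv)[:, 0]
    val = float(np.sqrt(np.mean((oof - train.y) ** 2)))
    if return_oof:
        return val, oof
    return val


def sigma_grid_values(grid: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = grid
    if lo <= 0 or step <= 0 or hi < lo:
        raise ValueError(f"invalid sigma grid {grid}")
    n = int(round((hi - lo) / step)) + 1
    vals = lo + step * np.arange(n)
    return vals[vals <= hi + 1e-9]


@dataclass
class SigmaSearch:
    """Result of the sigma grid search ('loop test')."""

    sigma: float
    table: list[tuple[float, float]]  # (sigma, CV RMSE kcal/mol)

    @property
    def best_rmse(self) -> float:
        return dict(self.table)[self.sigma]


def optimize_sigma(
    train: Dataset,
    subset: list[str],
    grid: tuple[float, float, float] = DEFAULT_SIGMA_GRID,
    cv: CVConfig = CVConfig(),
) -> SigmaSearch:
    """Grid-search sigma by CV RMSE; ties prefer the larger (smoother) sigma."""
    sigmas = sigma_grid_values(grid)
    if sigmas.size == 0:
        raise ValueError(f"empty sigma grid {grid}")
    oof = cv_predict(train, subset, sigmas, cv)
    y = train.y[:, None]
    rmses = np.sqrt(np.mean((oof - y) ** 2, axis=0))
    # argmax over reversed array -> largest sigma among exact ties
    best = sigmas.size - 1 - int(np.argmin(rmses[::-1]))
    return SigmaSearch(
        sigma=float(sigmas[best]),
        table=[(float(s), float(r)) for s, r in zip(sigmas, rmses)],
    )


@dataclass
class PipelineConfig:
    """End-to-end training settings."""

    train_fraction: float = 91.0 / 121.0
    n_train: int | None = None          # overrides train_fraction if set
    k: int = 10
    seed: int = 7
    sigma_grid: tuple[float, float, float] = DEFAULT_SIGMA_GRID
    top_k: int = 10
    max_subset: int = 6
    pls_components: int = 2

    def resolve_n_train(self, n: int) -> int:
        if self.n_train is not None:
            return self.n_train
        return int(round(self.train_fraction * n))


@dataclass
class PipelineResult:
    model: GRNNModel
    split: "object"        # sampling.SplitResult
    screening: "object"    # screening.ScreeningResult
    report: "object"       # validation.ValidationReport


def train_pipeline(data: Dataset, config: PipelineConfig | None = None):
    """Run the full correction workflow on a labelled descriptor table.

    Stages: SPXY split -> normalization (fit on train) -> PLS ranking ->
    CV subset selection with per-candidate sigma optimization -> final GRNN
    fit on the whole training set -> validation (R^2 on train, q^2cv from
    out-of-fold CV, q^2/RMSE/MAE on the SPXY test set).
    """
    from .sampling import spxy_split
    from .screening import fit_pls, rank_descriptors, select_final_subset
    from .validation import build_report

    config = config or PipelineConfig()
    if not data.has_reference:
        raise ValueError("train_pipeline requires reference_nci on every record")
    n = len(data)
    n_train = config.resolve_n_train(n)
    if n - n_train < 1:
        logger.warning("test set is empty (n_train=%d of %d)", n_train, n)

    split = spxy_split(data, n_train)
    train = data.subset(split.train_ids)
    test = data.subset(split.test_ids) if split.test_ids else None

    nmap = fit_normalization(train, include_target=True)
    Xn = nmap.transform_matrix(
        _subset_matrix(train, train.descriptor_names), train.descriptor_names
    )
    yn = np.asarray(nmap.apply_target(train.y), dtype=float)

    if len(train) >= 3:
        n_comp = min(config.pls_components, len(train) - 1,
                     len(train.descriptor_names))
        pls = fit_pls(Xn, yn, n_comp,
                      descriptor_names=train.descriptor_names)
        screening = rank_descriptors(pls, k=config.top_k)
    else:
        # degenerate training-set size: PLS needs >= 3 samples, so fall
        # back to an unranked shortlist led by the primary descriptor
        from .screening import ScreeningResult

        logger.warning(
            "training set of %d is too small for PLS screening; "
            "using the first %d descriptors unranked",
            len(train), config.top_k,
        )
        names = [PRIMARY_DESCRIPTOR] + [
            n for n in train.descriptor_names if n != PRIMARY_DESCRIPTOR
        ]
        screening = ScreeningResult(
            ranking=[], shortlist=names[: config.top_k]
        )

    cv = CVConfig(k=min(config.k, len(train)), seed=config.seed)
    screening = select_final_subset(
        screening, train, cv,
        sigma_grid=config.sigma_grid, max_size=config.max_subset,
    )
    subset = screening.final_subset
    search = optimize_sigma(train, subset, config.sigma_grid, cv)

    meta = {
        "sigma_grid": list(config.sigma_grid),
        "k": cv.k,
        "seed": config.seed,
        "subset": list(subset),
        "n_train": len(train),
        "sigma_table": search.table,
    }
    model = grnn_fit(train, subset, search.sigma, training_meta=meta)

    train_pred = grnn_predict(model, train, denormalize=True)
    _, oof = cv_rmse(train, subset, search.sigma, cv, return_oof=True)
    test_pred = test_obs = None
    if test is not None:
        test_pred = grnn_predict(model, test, denormalize=True)
        test_obs = test.y
    report = build_report(
        train_pred=train_pred, train_obs=train.y,
        oof_pred=oof, test_pred=test_pred, test_obs=test_obs,
    )
    return PipelineResult(model=model, split=split, screening=screening,
                          report=report)


@dataclass
class CorrectionResult:
    """Corrected NCI for one complex: corrected = DFT + correction."""

    id: str
    dft_nci: float
    corrected_nci: float

    @property
    def correction(self) -> float:
        return self.corrected_nci - self.dft_nci


def apply_correction(
    model: GRNNModel, data: Dataset
) -> list[CorrectionResult]:
    """Correct each record's DFT NCI using the trained network.

    The corrected value is the denormalized GRNN prediction; the correction
    term is its difference from the raw DFT value, so
    corrected = dft + correction holds exactly by construction.
    """
    preds = grnn_predict(model, data, denormalize=True)
    return [
        CorrectionResult(
            id=r.id,
            dft_nci=float(r.descriptors[PRIMARY_DESCRIPTOR]),
            corrected_nci=float(p),
        )
        for r, p in zip(data.records, preds)
    ]
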