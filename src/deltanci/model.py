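"""Model/Results front-end for the Δ-learning NCI correction.

:class:`GRNNCorrection` wraps the full workflow — SPXY partitioning, PLS
descriptor screening, CV-driven subset and smoothing-factor selection, GRNN
fitting and OECD-style validation — behind a fit/results interface:

>>> from deltanci import GRNNCorrection
>>> from deltanci.synthetic import generate_benchmark
>>> data, _ = generate_benchmark()
>>> res = GRNNCorrection(data, seed=7).fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> corrected = res.predict(new_dataset)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import Dataset, TableSchema, read_descriptor_table, save_model
from .grnn import (
    DEFAULT_SIGMA_GRID,
    CorrectionResult,
    PipelineConfig,
    apply_correction,
    train_pipeline,
)


class GRNNCorrection:
    """Δ-learning correction model for DFT non-covalent interaction energies.

    Parameters
    ----------
    data
        Labelled descriptor table: every record must carry ``dft_nci`` (the
        DFT interaction energy, kcal/mol) and a reference energy.
    train_fraction
        SPXY training fraction (default 91/121, the benchmark-set division).
    k
        Cross-validation fold count.
    seed
        Seed for fold shuffling; the rest of the pipeline is deterministic.
    sigma_grid
        ``(lo, hi, step)`` grid for the smoothing-factor loop test.
    top_k, max_subset
        PLS shortlist length and maximum GRNN input-subset size.
    """

    def __init__(
        self,
        data: Dataset,
        *,
        train_fraction: float = 91.0 / 121.0,
        n_train: int | None = None,
        k: int = 10,
        seed: int = 7,
        sigma_grid: tuple[float, float, float] = DEFAULT_SIGMA_GRID,
        top_k: int = 10,
        max_subset: int = 6,
        pls_components: int = 2,
    ) -> None:
        self.data = data
        self.config = PipelineConfig(
            train_fraction=train_fraction,
            n_train=n_train,
            k=k,
            seed=seed,
            sigma_grid=sigma_grid,
            top_k=top_k,
            max_subset=max_subset,
            pls_components=pls_components,
        )

    @classmethod
    def from_csv(
        cls, path, schema: TableSchema | None = None, **kwargs
    ) -> "GRNNCorrection":
        schema = schema or TableSchema(reference_required=True)
        return cls(read_descriptor_table(path, schema), **kwargs)

    def fit(self) -> "GRNNCorrectionResults":
        result = train_pipeline(self.data, self.config)
        return GRNNCorrectionResults(self, result)


@dataclass
class GRNNCorrectionResults:
    """Fitted correction model with diagnostics.

    Attributes
    ----------
    model : GRNNModel
        The trained kernel-regression network (patterns, targets, sigma).
    split, screening, report
        SPXY partition, descriptor-screening trace and validation metrics.
    """

    parent: GRNNCorrection
    _pipeline: object

    @property
    def model(self):
        return self._pipeline.model

    @property
    def split(self):
        return self._pipeline.split

    @property
    def screening(self):
        return self._pipeline.screening

    @property
    def report(self):
        return self._pipeline.report

    @property
    def sigma(self) -> float:
        return self.model.sigma

    @property
    def descriptors(self) -> list[str]:
        return list(self.model.descriptor_names)

    def predict(self, data: Dataset) -> list[CorrectionResult]:
        """Corrected NCIs (kcal/mol) for new complexes."""
        return apply_correction(self.model, data)

    def predict_frame(self, data: Dataset) -> pd.DataFrame:
        rows = self.predict(data)
        return pd.DataFrame(
            {
                "id": [r.id for r in rows],
                "dft_nci": [r.dft_nci for r in rows],
                "corrected_nci": [r.corrected_nci for r in rows],
                "correction": [r.correction for r in rows],
            }
        )

    def save(self, path) -> None:
        save_model(self.model, path)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels idiom."""
        rep = self.report
        lines = [
            "                GRNN Δ-correction results",
            "=" * 58,
            f"{'No. training complexes:':<32}{rep.n_train:>10d}",
            f"{'No. test complexes:':<32}{rep.n_test:>10d}",
            f"{'Input descriptors:':<32}{len(self.descriptors):>10d}",
            f"{'  ' + ', '.join(self.descriptors)}",
            f"{'Smoothing factor sigma:':<32}{self.sigma:>10.2f}",
            "-" * 58,
            f"{'RMSE train (kcal/mol):':<32}{rep.rmse_train:>10.3f}",
            f"{'MAE  train (kcal/mol):':<32}{rep.mae_train:>10.3f}",
            f"{'R^2 (train, Pearson^2):':<32}{rep.r2:>10.3f}",
            f"{'q^2cv (cross-validated):':<32}{rep.q2cv:>10.3f}",
        ]
        if rep.n_test:
            lines += [
                f"{'RMSE test (kcal/mol):':<32}{rep.rmse_test:>10.3f}",
                f"{'MAE  test (kcal/mol):':<32}{rep.mae_test:>10.3f}",
                f"{'q^2 (external test):':<32}{rep.q2:>10.3f}",
            ]
        lines += [
            "-" * 58,
            f"{'Over-fit flag (R^2-q^2cv>0.3):':<32}"
            f"{str(rep.overfit_flag):>10}",
            f"{'Valid (q^2, q^2cv > 0.5):':<32}{str(rep.valid):>10}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_correction(self, data: Dataset | None = None, ax=None):
        """Predicted-vs-reference scatter before and after correction."""
        import matplotlib.pyplot as plt

        if data is None:
            data = self.parent.data.subset(self.split.test_ids)
        rows = self.predict(data)
        ref = data.y
        dft = np.array([r.dft_nci for r in rows])
        cor = np.array([r.corrected_nci for r in rows])
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        lo = min(ref.min(), dft.min(), cor.min())
        hi = max(ref.max(), dft.max(), cor.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.scatter(ref, dft, s=18, alpha=0.7, label="DFT")
        ax.scatter(ref, cor, s=18, alpha=0.7, label="DFT-GRNN")
        ax.set_xlabel("reference NCI (kcal/mol)")
        ax.set_ylabel("calculated NCI (kcal/mol)")
        ax.legend()
        return ax
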