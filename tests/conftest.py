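import numpy as np
import pytest

from deltanci import GRNNCorrection
from deltanci.synthetic import SyntheticConfig, generate_benchmark

PLANTED = ("dft_nci", "dipole", "e_lumo1", "nve")


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark (121 complexes, seed 7) plus truth."""
    return generate_benchmark(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full pipeline runs for seeds 1..10 on the default benchmark.

    Shared by the subset-recovery and error-reduction checks; each entry
    carries the fitted results plus raw/corrected test-set RMSE (kcal/mol).
    """
    runs = []
    for seed in range(1, 11):
        data, truth = generate_benchmark(SyntheticConfig(seed=seed))
        res = GRNNCorrection(data, seed=seed).fit()
        test = data.subset(res.split.test_ids)
        raw = float(np.sqrt(np.mean((test.column("dft_nci") - test.y) ** 2)))
        runs.append(
            {
                "seed": seed,
                "results": res,
                "raw_test_rmse": raw,
                "corrected_test_rmse": res.report.rmse_test,
                "subset": tuple(sorted(res.descriptors)),
            }
        )
    return runs
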