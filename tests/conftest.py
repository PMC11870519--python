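import numpy as np
import pandas as pd
import pytest

from stresscore import prep
from stresscore.datatypes import ExpressionMatrix, SampleMetadata
from stresscore.pipeline import PipelineConfig, run_pipeline
from stresscore.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The package's standard desk-scale simulation (2000 genes, seed 7)."""
    return simulate_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def default_corrected(default_dataset):
    matrix, meta, truth = default_dataset
    filtered = prep.filter_zero_variance(matrix)
    logged = prep.log2p1_transform(filtered)
    corrected = prep.combat_correct(logged, meta)
    return filtered, logged, corrected, meta, truth


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One full default pipeline run (seed 7), shared across tests."""
    out = tmp_path_factory.mktemp("pipeline_run1")
    cfg = PipelineConfig(out_dir=str(out), seed=7)
    return run_pipeline(cfg)


def toy_two_stressor_dataset(
    n_genes: int = 40,
    reps: int = 4,
    separating_gene: int | None = 0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Small hand-built two-stressor dataset; optionally one gene perfectly
    separates stress from control in every batch."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cols, rows, data = [], [], []
    for stressor in ("heat", "salt"):
        for b in (1, 2):
            for treatment in ("control", "stress"):
                for r in range(reps):
                    name = f"{stressor}_b{b}_{treatment}_{r}"
                    cols.append(name)
                    rows.append(
                        {
                            "sample": name,
                            "batch": f"BP_{stressor}_{b}",
                            "stressor": stressor,
                            "treatment": treatment,
                            "tissue": "leaf",
                            "genotype": "B73",
                        }
                    )
                    x = rng.normal(5.0, 1.0, size=n_genes)
                    if separating_gene is not None:
                        x[separating_gene] = 10.0 if treatment == "stress" else 1.0
                    data.append(x)
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    matrix = ExpressionMatrix(values, scale_tag="batch_corrected")
    meta = SampleMetadata(pd.DataFrame(rows).set_index("sample"))
    return matrix, meta
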