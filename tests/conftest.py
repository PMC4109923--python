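import numpy as np
import pandas as pd
import pytest

import carcinogenome as cg
from carcinogenome.core import CONTROL, ExpressionDataset


def make_dataset(values: np.ndarray, *, n_controls: int, gene_prefix: str = "g",
                 time: float = 1.0, tissue: str = "liver", batch: str = "A",
                 compounds: list[str] | None = None) -> ExpressionDataset:
    """Hand-built dataset: first n_controls columns are controls, the rest
    treated (one compound per remaining column unless given)."""
    n_genes, n_samples = values.shape
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    n_treated = n_samples - n_controls
    if compounds is None:
        compounds = [f"cpd{i}" for i in range(n_treated)]
    sample_ids = [f"ctrl{i}" for i in range(n_controls)] + [f"s{i}" for i in range(n_treated)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "compound": [CONTROL] * n_controls + compounds,
            "dose_level": [None] * n_controls + ["high"] * n_treated,
            "time": time,
            "replicate": 1,
            "tissue": tissue,
            "is_control": [True] * n_controls + [False] * n_treated,
            "batch_id": batch,
        }
    ).set_index("sample_id")
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=sample_ids), meta)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal cohort reused across modules: clear planted modules,
    single high dose, two exposure times."""
    spec = cg.CohortSpec(
        n_genes=500, n_compounds=24, module_size=40, n_moa_modules=3,
        effect_size=2.0, dose_levels=("high",), dose_response=(1.0,),
        times=(4.0, 29.0), seed=101,
    )
    return cg.generate_cohort(spec)


@pytest.fixture(scope="session")
def single_module_cohort():
    """All carcinogens share one mechanism module: responders form a single
    well-separated group, ideal for clustering and projection checks."""
    spec = cg.CohortSpec(
        n_genes=500, n_compounds=24, module_size=50, n_moa_modules=1,
        effect_size=2.0, dose_levels=("high",), dose_response=(1.0,),
        times=(4.0, 29.0), seed=303,
    )
    return cg.generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effect anywhere; labels are pure noise."""
    spec = cg.CohortSpec(
        n_genes=500, n_compounds=20, effect_size=0.0,
        dose_levels=("high",), dose_response=(1.0,), times=(29.0,), seed=202,
    )
    return cg.generate_cohort(spec)
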