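import numpy as np
import pandas as pd
import pytest

from psoilcycle.catalog import default_catalog
from psoilcycle.profiling import KoCountTable, SampleMetadata
from psoilcycle.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def tiny_counts():
    """3 KOs × 3 samples with explicit annotated totals."""
    counts = pd.DataFrame(
        {"s1": [5.0, 3.0, 7.0], "s2": [10.0, 6.0, 14.0], "s3": [20.0, 12.0, 28.0]},
        index=["K00001", "K00002", "K00003"],
    )
    totals = pd.Series({"s1": 100.0, "s2": 200.0, "s3": 400.0})
    return KoCountTable(counts=counts, total_annotated=totals)


@pytest.fixture(scope="session")
def design_metadata():
    """2 sites × (CK, N, P) × 2 reps metadata with covariates."""
    rows = []
    rng = np.random.default_rng(0)
    for site in ("GZ", "JX"):
        for trt, (p, n) in {
            "CK": ("minusP", "minusN"),
            "N": ("minusP", "plusN"),
            "P": ("plusP", "minusN"),
        }.items():
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{site}_{trt}_{rep}",
                        "site": site,
                        "treatment": trt,
                        "p_contrast": p,
                        "n_contrast": n,
                        "replicate": rep,
                        "pH": 6.0 + rng.normal(0, 0.1),
                        "NP_ratio": 2.0 + rng.normal(0, 0.1),
                    }
                )
    return SampleMetadata(table=pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_study(catalog):
    """One default synthetic study (4 sites × 3 treatments × 3 reps)."""
    return simulate_study(SimulationConfig(seed=11), catalog)
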