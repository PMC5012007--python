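import numpy as np
import pandas as pd
import pytest

from adaptsig import Contrast, QuantTable, SimulationConfig, simulate_experiment


def make_table(values, samples=None, proteins=None, sites=None, scale="log2"):
    """Hand-build a small QuantTable from a dict {feature_id: row}."""
    fids = list(values)
    arr = np.array([values[f] for f in fids], dtype=float)
    n = arr.shape[1]
    if samples is None:
        # two groups x half replicates on one cell line
        half = n // 2
        samples = {
            **{f"a{r}": ("L1", "parental", r + 1) for r in range(half)},
            **{f"b{r}": ("L1", "resistant", r + 1) for r in range(n - half)},
        }
    names = list(samples)
    sm = pd.DataFrame(
        [
            {"cell_line": c, "state": s, "replicate": r}
            for (c, s, r) in samples.values()
        ],
        index=pd.Index(names, name="sample"),
    )
    fm = pd.DataFrame(
        {
            "protein_id": proteins or {f: f.split("_")[0] for f in fids},
            "site_label": sites or {f: (f.split("_")[1] if "_" in f else "") for f in fids},
        }
    ).loc[fids]
    fm.index = pd.Index(fids, name="feature_id")
    vdf = pd.DataFrame(arr, index=pd.Index(fids, name="feature_id"), columns=names)
    return QuantTable(values=vdf, feature_meta=fm, sample_meta=sm, scale=scale)


@pytest.fixture
def two_group_contrast():
    return Contrast("res", ("L1", "parental"), ("L1", "resistant"))


@pytest.fixture(scope="session")
def small_simulation():
    cfg = SimulationConfig(
        n_proteins=300,
        n_shared_up=15,
        n_persistent_down=15,
        n_resistant_up=15,
        n_resistant_down=15,
        seed=11,
    )
    return cfg, simulate_experiment(cfg)
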