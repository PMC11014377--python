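import numpy as np
import pandas as pd
import pytest

from agingtx import CountMatrix, SimConfig, generate_transcript_catalog, simulate_count_matrices


def make_sheet(n_young: int, n_aged: int) -> pd.DataFrame:
    names = [f"y{i+1}" for i in range(n_young)] + [f"a{i+1}" for i in range(n_aged)]
    return pd.DataFrame(
        {"age_group": ["6m"] * n_young + ["24m"] * n_aged, "cohort": "c1"},
        index=pd.Index(names, name="sample_id"),
    )


def make_matrix(values, n_young=None, n_aged=None, features=None) -> CountMatrix:
    arr = np.asarray(values, dtype=float)
    n = arr.shape[1]
    if n_young is None:
        n_young = n // 2
        n_aged = n - n_young
    sheet = make_sheet(n_young, n_aged)
    return CountMatrix(
        pd.DataFrame(arr, index=features or [f"f{i}" for i in range(arr.shape[0])],
                     columns=sheet.index),
        sheet,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated design shared by read-only tests."""
    cfg = SimConfig(n_genes=60, isoforms_per_gene=(2, 3), n_modules=2,
                    module_size=10, seed=101)
    catalog, event_truth = generate_transcript_catalog(cfg)
    gene_m, iso_m, gene_truth, switch_truth = simulate_count_matrices(catalog, cfg)
    return {
        "config": cfg, "catalog": catalog, "events": event_truth,
        "gene": gene_m, "isoform": iso_m, "genes": gene_truth,
        "switches": switch_truth,
    }
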