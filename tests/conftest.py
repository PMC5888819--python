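import numpy as np
import pandas as pd
import pytest

import mirpair as mp


@pytest.fixture(scope="session")
def reference_tables():
    return mp.load_reference_tables()


@pytest.fixture(scope="session")
def small_study():
    """A small paired study with a few planted effects, shared read-only."""
    cfg = mp.SyntheticConfig(
        n_subjects=60, n_genes=8, n_mirnas=12, seed=101,
        planted_gene_log_fc={"GENE0001": np.log(2.0), "GENE0002": np.log(0.5)},
        planted_mirna_log_fc={"mir-0001": np.log(2.0)},
        planted_seed_sites={("GENE0003", "mir-0001"): 2},
    )
    return mp.generate_all(cfg)


@pytest.fixture()
def toy_sample_map():
    subjects = ["s1", "s2", "s3"]
    samples = [f"{s}_{t}" for s in subjects for t in ("T", "N")]
    return pd.DataFrame(
        {"subject": [s for s in subjects for _ in range(2)],
         "tissue": ["tumor", "normal"] * 3},
        index=pd.Index(samples, name="sample"),
    )
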