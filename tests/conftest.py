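import numpy as np
import pandas as pd
import pytest

import histosplice as hs


def table_from_arrays(X, y, names=None) -> hs.DecisionTable:
    """Build a DecisionTable from plain arrays (test helper)."""
    X = np.asarray(X, dtype=np.uint8)
    names = names or [f"a{i + 1}" for i in range(X.shape[1])]
    index = pd.Index([f"x{i + 1}" for i in range(X.shape[0])], name="exon_id")
    return hs.DecisionTable(
        pd.DataFrame(X, index=index, columns=names),
        pd.Series(list(y), index=index),
    )


def random_table(rng, n_objects, n_attrs, p=0.3) -> hs.DecisionTable:
    X = (rng.random((n_objects, n_attrs)) < p).astype(np.uint8)
    y = np.where(rng.random(n_objects) < 0.5, "spliced_out", "included")
    if len(set(y)) < 2:  # force both classes
        y[0], y[1] = "spliced_out", "included"
    return table_from_arrays(X, y)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small dataset with one planted 2-condition rule at full penetrance."""
    rule = hs.PlantedRule(
        conditions=(("M01", "preceding", "present"), ("M02", "exon", "present")),
        target_class="spliced_out",
        penetrance=1.0,
    )
    cfg = hs.SyntheticConfig(
        n_genes=60, exons_per_gene=(5, 5), exon_length=(120, 200),
        n_marks=3, planted_rules=(rule,), background_rate=0.02,
        enrichment_fold=20.0, seed=7,
    )
    return hs.SyntheticDataset.generate(cfg)


@pytest.fixture(scope="session")
def planted_table(planted_dataset):
    table, internal, labeled, tracks = hs.build_synthetic_table(planted_dataset)
    return {"table": table, "internal": internal, "labeled": labeled,
            "tracks": tracks}
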