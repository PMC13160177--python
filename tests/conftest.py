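import warnings

import numpy as np
import pandas as pd
import pytest

from keju import KejuModel, PriorSpec, SynthConfig, generate
from keju.data import CountTable


@pytest.fixture(scope="session")
def small_dataset():
    """A small promoter+motif design with known truth, shared across tests."""
    cfg = SynthConfig(n_enhancers=40, n_controls=10, n_motifs=6,
                      n_covariates=2, n_replicates=2, barcodes=6, seed=101)
    return generate(cfg)


@pytest.fixture(scope="session")
def promoter_fit(small_dataset):
    """One short promoter-case fit reused by summary/trend/significance tests."""
    table, truth = small_dataset
    model = KejuModel.from_count_table(table, PriorSpec("promoter_motif"),
                                       G=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(chains=2, warmup=250, samples=250, seed=3)
    return model, res


def make_toy_frame(n_enhancers=4, barcodes=3, rna_batches=("b1", "b2"),
                   pooled=False, seed=0, controls=(), motifs=False,
                   covariates=False):
    """Hand-rolled toy count table builder, independent of the generator."""
    rng = np.random.default_rng(seed)
    rows = []
    enh = [f"e{i}" for i in range(n_enhancers)]
    for b_i, rb in enumerate(rna_batches):
        db = "d0" if pooled else f"d{b_i}"
        for e_i, e in enumerate(enh):
            for j in range(barcodes):
                bc = f"{e}_bc{j}"
                cond = "alternate" if b_i % 2 else "control"
                row = {
                    "barcode": bc, "dna_count": int(rng.integers(0, 60)),
                    "rna_count": int(rng.integers(0, 200)),
                    "enhancer": e, "rna_batch": rb, "dna_batch": db,
                    "condition": cond,
                    "is_control": e in controls,
                }
                if motifs:
                    row["motif"] = f"m{e_i % 2}"
                if covariates:
                    row["covariate"] = f"p{e_i % 2}"
                rows.append(row)
    df = pd.DataFrame(rows)
    if pooled:
        # one DNA pool: every barcode keeps one DNA count across RNA batches
        first = df.drop_duplicates(["enhancer", "barcode"]).set_index(
            ["enhancer", "barcode"])["dna_count"]
        df["dna_count"] = [first[(e, b)] for e, b in
                           zip(df["enhancer"], df["barcode"])]
    return df


@pytest.fixture
def toy_table():
    return CountTable(make_toy_frame(controls=("e0",)))
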