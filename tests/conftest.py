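import numpy as np
import pandas as pd
import pytest

from sexlabel import meta_labels, sexinfer, synthgen


@pytest.fixture(scope="session")
def small_corpus():
    cfg = synthgen.SimConfig(n_studies=40, samples_per_study=(6, 14),
                             swap_rate=0.03, missing_rate=0.1, seed=11)
    return synthgen.generate_corpus(cfg)


@pytest.fixture(scope="session")
def trained(small_corpus):
    """Model trained quickly on the small corpus (reduced alpha grid)."""
    c = small_corpus
    samples, _ = meta_labels.label_metadata(c.meta)
    labeled = samples[samples["metadata_sex"].isin(["female", "male"])]
    labeled = labeled.rename(columns={"metadata_sex": "sex"})
    groups = sexinfer.build_study_groups(
        c.meta[["sample_id", "study_id"]].drop_duplicates())
    train, test = sexinfer.construct_train_test(labeled, groups, seed=5)
    X = c.expression.loc[train["sample_id"]]
    y = (train["sex"] == "male").to_numpy(int)
    model = sexinfer.nested_cv_fit(
        X, y, train["group"].to_numpy(), feature_table=c.genes,
        alpha_grid=(0.5, 1.0), n_lambda=12, seed=5)
    return c, model, train, test


@pytest.fixture(scope="session")
def lexicons():
    cells, drugs, controls = synthgen.generate_lexicon_fixtures(seed=0)
    return cells, drugs, controls


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def truth_of(corpus) -> pd.Series:
    return corpus.truth.set_index("sample_id")["true_sex"]
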