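"""Shared fixtures: small synthetic corpora and trained surrogate models.

Sizes are deliberately modest (tens of sequences, tens of Monte-Carlo
shuffles) so the whole suite runs in minutes while still exercising every
pipeline stage on separable data.
"""

import numpy as np
import pytest

import mirfuse as mf


@pytest.fixture(scope="session")
def small_dataset():
    """60 designed hairpins vs 60 dinucleotide-shuffled negatives."""
    return mf.gen_dataset(n_pos=60, n_neg=60, rng=11, n_shuffles=15)


@pytest.fixture(scope="session")
def committee(small_dataset):
    datasets = {
        space: small_dataset.labeled(space)
        for space in ("triplet32", "hybrid34", "seqstruct512")
    }
    return mf.train_committee(datasets, seed=1)


@pytest.fixture(scope="session")
def committee_decisions_matrix(small_dataset, committee):
    from mirfuse.base_committee import committee_decision_matrix
    from mirfuse.feature_extraction import build_feature_bundle

    rng = np.random.default_rng(2)
    bundles = [
        build_feature_bundle(mf.fold(seq), n_shuffles=15, rng=rng)
        for seq in small_dataset.sequences
    ]
    return committee_decision_matrix(bundles, committee)


@pytest.fixture(scope="session")
def trained_fusion(small_dataset, committee_decisions_matrix):
    X = committee_decisions_matrix.astype(float)
    y = small_dataset.labels.astype(float)
    net, record = mf.train_elm(X, y, restarts=50, rng=3)
    return net, record


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
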