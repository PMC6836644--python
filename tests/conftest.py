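import numpy as np
import pytest

from mcscreen import (
    CompoundTable,
    FeatureClustering,
    MCSModel,
    SyntheticSpec,
    build_mcs,
    cluster_features,
    compact_roster,
    generate_dataset,
    partition_rows,
)
from mcscreen.mcs_model import TrainedClusterClassifier


@pytest.fixture
def tiny_table():
    """Hand-built 6-compound table: 4 bits, 1 discrete + 1 continuous descriptor."""
    return CompoundTable(
        ids=[f"CMP{i}" for i in range(6)],
        bits=np.array(
            [
                [1, 1, 0, 0],
                [1, 0, 1, 0],
                [1, 1, 1, 0],
                [0, 0, 0, 1],
                [0, 1, 0, 1],
                [0, 0, 1, 1],
            ],
            dtype=np.uint8,
        ),
        bit_names=["fp0000", "fp0001", "fp0002", "fp0003"],
        descriptors=np.array(
            [[3, 0.5], [4, 1.5], [5, 0.9], [1, -0.4], [0, -1.2], [2, -0.8]],
            dtype=float,
        ),
        descriptor_names=["dd00", "cd00"],
        descriptor_types=["discrete", "continuous"],
        labels=np.array(
            ["Active", "Active", "Active", "Inactive", "Inactive", "Inactive"],
            dtype=object,
        ),
    )


class FixedProbEstimator:
    """Stub classifier emitting a preset Active probability per compound."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)
        self.classes_ = np.array(["Active", "Inactive"], dtype=object)

    def predict_proba(self, X):
        p = self.probs
        if p.size == 1:
            p = np.full(len(X), p[0])
        return np.column_stack([p, 1.0 - p])


def make_stub_model(table, cluster_probs, objective="MCC", voting="majority"):
    """MCSModel whose k inner classifiers emit fixed probabilities.

    ``cluster_probs`` is a list of per-cluster probability settings (scalar or
    per-compound vector); the feature columns are dealt evenly just to satisfy
    the clustering contract.
    """
    k = len(cluster_probs)
    cols = table.feature_names
    clusters = [list(cols[i::k]) for i in range(k)]
    clustering = FeatureClustering(k=k, clusters=clusters)
    classifiers = [
        TrainedClusterClassifier(
            cluster_index=i + 1,
            spec_name="stub",
            params={},
            estimator=FixedProbEstimator(np.atleast_1d(p)),
            objective=objective,
            cv_score=1.0,
            cv_mcc=1.0,
            columns=clusters[i],
        )
        for i, p in enumerate(cluster_probs)
    ]
    return MCSModel(
        objective=objective, classifiers=classifiers, clustering=clustering, voting=voting
    )


@pytest.fixture
def stub_model_factory():
    return make_stub_model


STRONG_SPEC = SyntheticSpec(n_active=1000, n_inactive=1000, seed=7)


@pytest.fixture(scope="session")
def strong_data():
    """Strong-signal synthetic table (defaults: 40/256 informative bits,
    p_active=0.8 vs p_inactive=0.2) with a 4-group partition."""
    table, informative = generate_dataset(STRONG_SPEC)
    groups = partition_rows(table, 4, seed=7)
    return table, informative, groups


@pytest.fixture(scope="session")
def strong_models(strong_data):
    """MCC- and PPV-optimized ensembles trained on groups 1-3 (compact roster)."""
    table, _, groups = strong_data
    train_rows = [r for r, cid in enumerate(table.ids) if groups.assignment[cid] != 4]
    test_rows = groups.group_indices(table, 4)
    train = table.subset(train_rows)
    clustering = cluster_features(train, k=3)
    model_mcc = build_mcs(train, clustering, "MCC", roster=compact_roster(), seed=7)
    model_ppv = build_mcs(train, clustering, "PPV", roster=compact_roster(), seed=7)
    return {
        "train": train,
        "test": table.subset(test_rows),
        "clustering": clustering,
        "mcc": model_mcc,
        "ppv": model_ppv,
    }
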