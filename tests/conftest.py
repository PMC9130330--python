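import itertools

import numpy as np
import pandas as pd
import pytest

from bosme.bayesnet import Dag, fit_mle, log_likelihood_score
from bosme.data_model import DatasetTable, FeatureSchema
from bosme.synthdata import GroundTruthSpec, random_ground_truth_bn, sample_imbalanced_dataset


@pytest.fixture
def binary_schema():
    return [FeatureSchema("A", "categorical", ("0", "1")),
            FeatureSchema("B", "categorical", ("0", "1"))]


@pytest.fixture
def mixed_table():
    """Small mixed-feature binary table for plumbing tests."""
    feats = [FeatureSchema("color", "categorical", ("red", "blue")),
             FeatureSchema("size", "continuous")]
    df = pd.DataFrame({
        "color": ["red", "blue", "red", "blue", "red", "red"],
        "size": [1.0, 2.5, 3.25, 0.5, 1.75, 2.0],
        "V": ["-", "-", "-", "-", "+", "+"],
    })
    return DatasetTable(feats, "V", df)


@pytest.fixture
def discrete_problem():
    """Class-conditional ground-truth pair with a clearly separable signal."""
    spec = GroundTruthSpec(n_features=4, kinds=[2, 2, 2, 2], m_plus=60, m_minus=340,
                           arc_density=1.0, divergence_knob=1.5, seed=3)
    bn_pos = random_ground_truth_bn(spec, "positive")
    bn_neg = random_ground_truth_bn(spec, "negative")
    table = sample_imbalanced_dataset(bn_pos, bn_neg, spec.m_plus, spec.m_minus, seed=7)
    return spec, bn_pos, bn_neg, table


def all_three_node_dags(nodes):
    """Brute-force enumeration of every DAG on three labelled nodes (25 of them)."""
    possible = list(itertools.permutations(nodes, 2))
    dags = []
    for mask in range(2 ** len(possible)):
        arcs = [possible[i] for i in range(len(possible)) if mask >> i & 1]
        try:
            dags.append(Dag(nodes, arcs))
        except Exception:
            continue
    return dags


def exhaustive_best_score(df, schemas):
    """Independent oracle: the maximum fitted log-likelihood over all 3-node DAGs."""
    return max(log_likelihood_score(d, df, schemas)
               for d in all_three_node_dags([s.name for s in schemas]))
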