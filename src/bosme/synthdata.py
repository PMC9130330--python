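"""Ground-truth generators for end-to-end testing without external downloads.

Imbalanced problems are generated *class-conditionally*: one random Bayesian
network per class over a shared feature schema, with the negative-class
network derived from the positive one by a controlled parameter perturbation
(the divergence knob).  This construction keeps the Bayes-optimal and
cost-optimal decision rules exactly computable by enumeration on small
discrete problems.  A canonical fixture suite mimics the shapes of common
benchmark tables: an all-categorical problem of 1728 rows with a 7.75%
minority, a mixed 462-row problem, and an all-continuous 306-row problem.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import (BayesianNetwork, Dag, DiscreteCpd, LinearGaussianCpd,
                       joint_probability, logic_sample)
from .data_model import (POS, NEG, DatasetTable, FeatureSchema,
                         PreconditionError, save_schema, write_dataset)


@dataclass
class GroundTruthSpec:
    """Recipe for a pair of class-conditional ground-truth networks."""

    n_features: int = 4
    kinds: list | None = None  # per-feature: int (=categorical level count) or "continuous"
    arc_density: float = 1.0  # expected parents per node
    dirichlet_alpha: float = 1.0
    clg_ranges: dict = field(default_factory=lambda: {
        "intercept": (-1.0, 1.0), "coef": (-1.0, 1.0), "sd": (0.5, 1.5)})
    m_plus: int = 100
    m_minus: int = 400
    divergence_knob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kinds is None:
            self.kinds = [2] * self.n_features
        if len(self.kinds) != self.n_features:
            raise PreconditionError("kinds length must equal n_features")
        if self.m_plus > self.m_minus:
            raise PreconditionError("m_plus must not exceed m_minus")
        if self.arc_density < 0 or self.dirichlet_alpha <= 0:
            raise PreconditionError("invalid arc_density or dirichlet_alpha")

    def schemas(self) -> list[FeatureSchema]:
        out = []
        for i, kind in enumerate(self.kinds):
            name = f"x{i + 1}"
            if kind == "continuous":
                out.append(FeatureSchema(name, "continuous"))
            else:
                levels = tuple(f"l{j}" for j in range(int(kind)))
                out.append(FeatureSchema(name, "categorical", levels))
        return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def random_ground_truth_bn(spec: GroundTruthSpec, class_side: str = "positive") -> BayesianNetwork:
    """Random BN for one class side; the negative side is a deterministic
    perturbation (by ``divergence_knob``) of the positive side's parameters."""
    if class_side not in ("positive", "negative"):
        raise PreconditionError(f"unknown class side {class_side!r}")
    rng = np.random.default_rng(spec.seed)
    schemas = spec.schemas()
    names = [s.name for s in schemas]
    kinds = {s.name: s.kind for s in schemas}
    order = [names[i] for i in rng.permutation(len(names))]
    p_arc = 0.0 if spec.n_features < 2 else min(1.0, 2 * spec.arc_density / (spec.n_features - 1))
    dag = Dag(names)
    for i, j in itertools.combinations(range(len(order)), 2):
        p, c = order[i], order[j]
        if kinds[c] == "categorical" and kinds[p] == "continuous":
            continue  # CLG parent rule
        if rng.random() < p_arc:
            dag.add_arc(p, c)

    by_name = {s.name: s for s in schemas}
    lo_b, hi_b = spec.clg_ranges["intercept"]
    lo_c, hi_c = spec.clg_ranges["coef"]
    lo_s, hi_s = spec.clg_ranges["sd"]

    cpds: dict = {}
    for node in names:
        s = by_name[node]
        disc = tuple(p for p in dag.parents(node) if kinds[p] == "categorical")
        cont = tuple(p for p in dag.parents(node) if kinds[p] == "continuous")
        if s.is_categorical:
            k = len(s.levels)
            plv = tuple(by_name[p].levels for p in disc)
            table = {cfg: rng.dirichlet(np.full(k, spec.dirichlet_alpha))
                     for cfg in itertools.product(*plv)}
            cpds[node] = DiscreteCpd(node, s.levels, disc, plv, table)
        else:
            plv = tuple(by_name[p].levels for p in disc)
            params = {}
            for cfg in itertools.product(*plv):
                b0 = rng.uniform(lo_b, hi_b)
                coefs = rng.uniform(lo_c, hi_c, size=len(cont))
                sd = rng.uniform(lo_s, hi_s)
                params[cfg] = (float(b0), coefs, float(sd))
            cpds[node] = LinearGaussianCpd(node, disc, plv, cont, params)

    if class_side == "negative":
        # perturb on the same rng stream: deterministic for a given spec
        knob = spec.divergence_knob
        for node in names:
            cpd = cpds[node]
            if isinstance(cpd, DiscreteCpd):
                for cfg, vec in cpd.table.items():
                    logits = np.log(np.clip(vec, 1e-12, None))
                    cpd.table[cfg] = _softmax(logits + knob * rng.standard_normal(len(vec)))
            else:
                for cfg, (b0, coefs, sd) in cpd.params.items():
                    cpd.params[cfg] = (b0 + knob * rng.standard_normal(), coefs, sd)
    return BayesianNetwork(dag, cpds, schemas)


def sample_imbalanced_dataset(bn_pos: BayesianNetwork, bn_neg: BayesianNetwork,
                              m_plus: int, m_minus: int, seed=None,
                              class_name: str = "V") -> DatasetTable:
    """m+ rows from the positive network and m− from the negative, labelled
    and shuffled; the class balance matches the requested counts exactly."""
    if [s.name for s in bn_pos.schemas] != [s.name for s in bn_neg.schemas]:
        raise PreconditionError("the two networks must share a schema")
    if m_plus < 1:
        raise PreconditionError("at least one minority row is required")
    if m_plus > m_minus:
        raise PreconditionError("m_plus must not exceed m_minus")
    ss = np.random.SeedSequence(seed)
    s_pos, s_neg, s_shuf = ss.spawn(3)
    pos = logic_sample(bn_pos, m_plus, seed=s_pos)
    neg = logic_sample(bn_neg, m_minus, seed=s_neg)
    pos[class_name] = POS
    neg[class_name] = NEG
    df = pd.concat([pos, neg], ignore_index=True)
    perm = np.random.default_rng(s_shuf).permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    table = DatasetTable(list(bn_pos.schemas), class_name, df)
    table.validate()
    return table


def kl_joint(bn_true: BayesianNetwork, bn_est: BayesianNetwork,
             floor: float = 1e-12) -> float:
    """KL(true ‖ estimated) over the full joint of small discrete networks.

    Estimated cell probabilities are floored at ``floor`` so the divergence
    stays finite when the maximum-likelihood estimate assigns zero mass to a
    configuration unseen in the training sample; the floor only matters for
    such zero cells and leaves the ordering of fits essentially untouched.
    """
    from .bayesnet import enumerate_joint

    p = enumerate_joint(bn_true)
    q = enumerate_joint(bn_est)
    return float(sum(pv * np.log(pv / max(q[cfg], floor))
                     for cfg, pv in p.items() if pv > 0))


def bayes_error(bn_pos: BayesianNetwork, bn_neg: BayesianNetwork,
                p_plus: float) -> float:
    """Exact Bayes error of the induced problem by enumeration (discrete only)."""
    names = [s.name for s in bn_pos.schemas]
    levels = [s.levels for s in bn_pos.schemas]
    err = 0.0
    for cfg in itertools.product(*levels):
        inst = dict(zip(names, cfg))
        jp = p_plus * joint_probability(bn_pos, inst)
        jn = (1 - p_plus) * joint_probability(bn_neg, inst)
        err += min(jp, jn)
    return err


# ---------------------------------------------------------------------------
# Fixture suite

_FIXTURES = {
    # all-categorical, car-evaluation shape: 1728 rows, 7.75% minority
    "car_like": dict(kinds=[4, 4, 4, 3, 3, 3], m_plus=134, m_minus=1594,
                     arc_density=1.0, divergence_knob=1.5),
    # mixed, saheart shape: 462 rows, 1 categorical + 8 continuous, 34.63% minority
    "saheart_like": dict(kinds=[2] + ["continuous"] * 8, m_plus=160, m_minus=302,
                         arc_density=1.0, divergence_knob=1.0),
    # all-continuous, haberman shape: 306 rows, 26.47% minority
    "haberman_like": dict(kinds=["continuous"] * 3, m_plus=81, m_minus=225,
                          arc_density=1.0, divergence_knob=1.0),
}


def make_fixture_suite(out_dir, master_seed: int = 0) -> dict:
    """Write the canonical CSV + schema fixtures and a manifest.

    Each fixture records its generating seed and the true network parameters,
    so regeneration from the manifest is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": master_seed, "fixtures": {}}
    for idx, (name, cfg) in enumerate(_FIXTURES.items()):
        seed = master_seed * 1000 + idx
        spec = GroundTruthSpec(n_features=len(cfg["kinds"]), kinds=list(cfg["kinds"]),
                               arc_density=cfg["arc_density"], m_plus=cfg["m_plus"],
                               m_minus=cfg["m_minus"],
                               divergence_knob=cfg["divergence_knob"], seed=seed)
        bn_pos = random_ground_truth_bn(spec, "positive")
        bn_neg = random_ground_truth_bn(spec, "negative")
        table = sample_imbalanced_dataset(bn_pos, bn_neg, spec.m_plus, spec.m_minus,
                                          seed=seed + 500)
        csv_path = out / f"{name}.csv"
        write_dataset(table, csv_path)
        save_schema(out / f"{name}.schema.yaml", table.features, table.class_name,
                    minority_label=POS)
        with open(out / f"{name}.bn.json", "w") as fh:
            json.dump({"positive": bn_pos.to_dict(), "negative": bn_neg.to_dict()}, fh)
        manifest["fixtures"][name] = {
            "seed": seed, "sample_seed": seed + 500,
            "rows": table.n_rows, "m_plus": spec.m_plus, "m_minus": spec.m_minus,
            "p_plus": spec.m_plus / (spec.m_plus + spec.m_minus),
            "csv": csv_path.name,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
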