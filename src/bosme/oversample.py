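"""Minority over-sampling: the Bayesian-network method (BOSME) and a SMOTE baseline.

BOSME learns a maximum-likelihood Bayesian network from the minority rows
(class column excluded) by hill climbing, then forward-samples as many
synthetic minority rows as needed to lift the minority share of the enlarged
table to a target proportion q.  The synthetic count solving
(m+ + n)/(M + n) = q is n = round((q·M − m+)/(1 − q)), rounded
half-away-from-zero.

The SMOTE baseline interpolates each synthetic row between a random minority
instance and one of its k nearest minority neighbours (Gower-style distance:
absolute difference standardized by the feature's minority sd for continuous
features, 0/1 mismatch for categorical); categorical values are copied at
random from the instance/neighbour pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayesnet import BayesianNetwork, LearnConfig, fit_mle, hill_climb, logic_sample
from .data_model import ClassBalance, DatasetTable, PreconditionError, class_balance


@dataclass(frozen=True)
class OversamplePlan:
    """Target minority proportion q and the synthetic count n achieving it."""

    q: float
    n: int
    source_balance: ClassBalance

    def __post_init__(self):
        if not self.source_balance.p_plus < self.q < 1:
            raise PreconditionError("q must lie in (p_plus, 1)")
        if self.n < 0:
            raise PreconditionError("n must be non-negative")

    @property
    def achieved_proportion(self) -> float:
        b = self.source_balance
        return (b.m_plus + self.n) / (b.M + self.n)


def required_n(balance: ClassBalance, q: float) -> int:
    """Synthetic minority count n = round((q·M − m+)/(1 − q)), half away from zero.

    The achieved proportion (m+ + n)/(M + n) then deviates from q by at most
    1/(M + n).
    """
    if not balance.p_plus < q < 1:
        raise PreconditionError(
            f"q={q} must lie strictly between the minority proportion "
            f"{balance.p_plus:.4f} and 1")
    x = (q * balance.M - balance.m_plus) / (1.0 - q)
    return int(math.floor(x + 0.5))  # x > 0 here, so this is half-away-from-zero


def _plan(table: DatasetTable, minority_label: str, q: float) -> tuple[ClassBalance, OversamplePlan]:
    balance = class_balance(table, minority_label)
    n = required_n(balance, q)
    return balance, OversamplePlan(q=q, n=n, source_balance=balance)


def bosme_oversample(
    table: DatasetTable,
    minority_label: str,
    q: float,
    learn_config: LearnConfig | None = None,
    seed=None,
) -> tuple[DatasetTable, BayesianNetwork, OversamplePlan]:
    """Enlarge ``table`` with BN-generated synthetic minority rows.

    Steps: extract the minority subset (class column dropped); learn a
    Bayesian network on it (hill climbing + MLE); forward-sample n rows;
    assign them the minority label and append after the original rows, order
    preserved.  A fixed seed gives byte-identical output.
    """
    table.validate()
    balance, plan = _plan(table, minority_label, q)
    minority = table.df[table.df[table.class_name] == minority_label]
    if len(minority) < 2:
        raise PreconditionError("minority subset too small to fit a network")
    X_min = minority[table.feature_names].reset_index(drop=True)
    dag = hill_climb(X_min, table.features, learn_config or LearnConfig())
    bn = fit_mle(dag, X_min, table.features)
    synth = logic_sample(bn, plan.n, seed=seed)
    synth[table.class_name] = minority_label
    enlarged = pd.concat([table.df, synth], ignore_index=True)
    out = replace(table, df=enlarged, provenance="enlarged")
    return out, bn, plan


def smote_baseline(
    table: DatasetTable,
    minority_label: str,
    q: float,
    k: int = 5,
    seed=None,
) -> DatasetTable:
    """SMOTE-style over-sampling to minority proportion q (see module docstring)."""
    table.validate()
    balance, plan = _plan(table, minority_label, q)
    minority = table.df[table.df[table.class_name] == minority_label]
    m = len(minority)
    if m < k + 1:
        raise PreconditionError(f"SMOTE with k={k} needs at least {k + 1} minority rows")
    rng = np.random.default_rng(seed)

    cat = [f.name for f in table.features if f.is_categorical]
    cont = [f.name for f in table.features if not f.is_categorical]
    Xc = minority[cont].to_numpy(dtype=float) if cont else np.empty((m, 0))
    # Gower-style distance matrix on the minority subset
    dist = np.zeros((m, m))
    if cont:
        sds = Xc.std(axis=0)
        sds[sds == 0] = 1.0
        Z = Xc / sds
        dist += np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    for name in cat:
        v = minority[name].to_numpy()
        dist += (v[:, None] != v[None, :]).astype(float)
    np.fill_diagonal(dist, np.inf)
    # deterministic k-nearest with index tie-break
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rows = []
    for _ in range(plan.n):
        i = int(rng.integers(m))
        j = int(neighbors[i, rng.integers(k)])
        lam = float(rng.random())
        rec = {}
        for name in cont:
            a = Xc[i, cont.index(name)]
            b = Xc[j, cont.index(name)]
            rec[name] = a + lam * (b - a)
        for name in cat:
            pick = int(rng.integers(2))
            rec[name] = minority[name].iloc[i if pick == 0 else j]
        rec[table.class_name] = minority_label
        rows.append(rec)
    synth = pd.DataFrame(rows, columns=list(table.df.columns)) if rows else \
        table.df.iloc[0:0].copy()
    enlarged = pd.concat([table.df, synth], ignore_index=True)
    return replace(table, df=enlarged, provenance="enlarged")


# ---------------------------------------------------------------------------
# sklearn/imblearn-style estimator facades


class _BaseOverSampler:
    """Shared params/resample plumbing for the estimator facades.

    ``fit_resample(X, y)`` follows the imbalanced-learn convention: X is a
    DataFrame (schema inferred if not given), y the class labels; the minority
    label is the rarer one.  The target proportion comes from ``q`` directly
    or from ``gamma`` via the Folk-theorem formula.
    """

    def __init__(self, q: float | None = None, gamma: float | None = None,
                 random_state=None):
        self.q = q
        self.gamma = gamma
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return dict(self.__dict__)

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _resolve_q(self, balance: ClassBalance) -> float:
        from .costsense import CostSpec, target_q

        if (self.q is None) == (self.gamma is None):
            raise PreconditionError("exactly one of q and gamma must be set")
        if self.q is not None:
            return self.q
        return target_q(balance, CostSpec.from_gamma(self.gamma))

    def _table(self, X: pd.DataFrame, y) -> tuple[DatasetTable, str]:
        from .data_model import infer_schema

        y = pd.Series(np.asarray(y, dtype=object), name="__class__")
        counts = y.value_counts()
        minority = str(counts.index[-1])
        df = X.copy()
        df["__class__"] = y.astype(str).to_numpy()
        table = DatasetTable(infer_schema(X), "__class__", df)
        return table, minority

    def fit_resample(self, X: pd.DataFrame, y):
        table, minority = self._table(X, y)
        balance = class_balance(table, minority)
        q = self._resolve_q(balance)
        out = self._resample_table(table, minority, q)
        self.sampling_plan_ = getattr(self, "sampling_plan_", None)
        return out.df[table.feature_names], out.df["__class__"].to_numpy()


class BOSMEOverSampler(_BaseOverSampler):
    """Estimator facade over :func:`bosme_oversample`.

    Fitted attributes: ``network_`` (the learned Bayesian network) and
    ``sampling_plan_`` (q, n and the source class balance).
    """

    def __init__(self, q: float | None = None, gamma: float | None = None,
                 epsilon: float = 1e-6, max_parents: int | None = None,
                 random_state=None):
        super().__init__(q=q, gamma=gamma, random_state=random_state)
        self.epsilon = epsilon
        self.max_parents = max_parents

    def _resample_table(self, table, minority, q):
        cfg = LearnConfig(epsilon=self.epsilon, max_parents=self.max_parents)
        out, bn, plan = bosme_oversample(table, minority, q, cfg, seed=self.random_state)
        self.network_ = bn
        self.sampling_plan_ = plan
        return out


class SMOTEOverSampler(_BaseOverSampler):
    """Estimator facade over :func:`smote_baseline`."""

    def __init__(self, q: float | None = None, gamma: float | None = None,
                 k: int = 5, random_state=None):
        super().__init__(q=q, gamma=gamma, random_state=random_state)
        self.k = k

    def _resample_table(self, table, minority, q):
        out = smote_baseline(table, minority, q, k=self.k, seed=self.random_state)
        self.sampling_plan_ = None
        return out
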