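"""Bayesian networks: MLE fitting, log-likelihood scoring, hill climbing, sampling.

Three families are supported, chosen by the feature schemas:

* **discrete** — every node categorical, with conditional probability tables;
* **gaussian** — every node continuous; each node is Normal with mean linear
  in its (continuous) parents;
* **clg** (conditional linear Gaussian) — mixed; a categorical node may only
  have categorical parents, and a continuous node is Gaussian per joint
  configuration of its categorical parents, with mean linear in its
  continuous parents.

Structure search is steepest-ascent hill climbing over single-arc additions,
removals and reversals from the empty graph, scored by the fitted
log-likelihood (natural log, MLE variance).  Because pure log-likelihood
never decreases when an arc is added on training data, termination relies on
a strict minimum gain ``epsilon`` and an optional parent cap.  Sampling is
logic (forward) sampling in topological order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureSchema, PreconditionError

LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """Model fitting failed (CLI exit code 3)."""


class CycleError(PreconditionError):
    """An arc set contains (or a mutation would create) a directed cycle."""


# ---------------------------------------------------------------------------
# DAG


class Dag:
    """Directed acyclic graph over an ordered node list.

    Node declaration order is preserved and used as the deterministic
    tie-break in topological sorting.
    """

    def __init__(self, nodes, arcs=()):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise PreconditionError("duplicate node names")
        self._order = {n: i for i, n in enumerate(self.nodes)}
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        for p, c in arcs:
            self.add_arc(p, c)

    @property
    def arcs(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self._parents.items() for p in ps}

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._parents[node], key=self._order.__getitem__))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._children[node], key=self._order.__getitem__))

    def has_arc(self, parent: str, child: str) -> bool:
        return parent in self._parents[child]

    def _reaches(self, src: str, dst: str) -> bool:
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self._children[u])
        return False

    def add_arc(self, parent: str, child: str) -> None:
        if parent not in self._order or child not in self._order:
            raise PreconditionError(f"unknown node in arc ({parent}, {child})")
        if parent == child:
            raise CycleError(f"self-loop {parent}->{child}")
        if self._reaches(child, parent):
            raise CycleError(f"arc {parent}->{child} would create a cycle")
        self._parents[child].add(parent)
        self._children[parent].add(child)

    def remove_arc(self, parent: str, child: str) -> None:
        self._parents[child].discard(parent)
        self._children[parent].discard(child)

    def would_be_acyclic(self, parent: str, child: str) -> bool:
        return parent != child and not self._reaches(child, parent)

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.arcs)

    def __eq__(self, other):
        return isinstance(other, Dag) and self.nodes == other.nodes and self.arcs == other.arcs

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        lines += [f'  "{n}";' for n in self.nodes]
        lines += [f'  "{p}" -> "{c}";' for p, c in sorted(self.arcs)]
        lines.append("}")
        return "\n".join(lines)


def topological_order(dag: Dag) -> list[str]:
    """Kahn's algorithm; among ready nodes, declaration order wins."""
    indeg = {n: len(dag._parents[n]) for n in dag.nodes}
    ready = [n for n in dag.nodes if indeg[n] == 0]
    out: list[str] = []
    while ready:
        ready.sort(key=dag._order.__getitem__)
        u = ready.pop(0)
        out.append(u)
        for c in dag.children(u):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(out) != len(dag.nodes):
        raise CycleError("cycle detected in topological sort")
    return out


# ---------------------------------------------------------------------------
# Conditional distributions


@dataclass
class DiscreteCpd:
    """CPT of a categorical child given its categorical parents.

    One probability vector per joint parent configuration; configurations
    unseen in the training data carry a uniform vector and are flagged in
    ``fallback_configs``.
    """

    child: str
    levels: tuple[str, ...]
    parents: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: dict[tuple, np.ndarray]
    fallback_configs: frozenset = frozenset()

    def prob(self, value: str, parent_values: tuple) -> float:
        vec = self.table[tuple(parent_values)]
        return float(vec[self.levels.index(value)])


@dataclass
class LinearGaussianCpd:
    """Gaussian child: per categorical-parent configuration, the mean is
    ``intercept + coefs · continuous_parent_values`` and sd is fixed.

    Configurations with fewer than 2 rows or a singular design fall back to
    the pooled fit (flagged); the sd never goes below ``sigma_floor``.
    """

    child: str
    disc_parents: tuple[str, ...]
    disc_parent_levels: tuple[tuple[str, ...], ...]
    cont_parents: tuple[str, ...]
    params: dict[tuple, tuple[float, np.ndarray, float]]  # config -> (b0, coefs, sd)
    fallback_configs: frozenset = frozenset()

    def mean_sd(self, disc_values: tuple, cont_values: np.ndarray) -> tuple[float, float]:
        b0, coefs, sd = self.params[tuple(disc_values)]
        return float(b0 + coefs @ np.asarray(cont_values, dtype=float)), sd

    def logpdf(self, value: float, disc_values: tuple, cont_values) -> float:
        mu, sd = self.mean_sd(disc_values, np.asarray(cont_values, dtype=float))
        z = (value - mu) / sd
        return -0.5 * (LOG_2PI + z * z) - math.log(sd)


@dataclass
class BayesianNetwork:
    """DAG plus one conditional distribution per node."""

    dag: Dag
    cpds: dict[str, DiscreteCpd | LinearGaussianCpd]
    schemas: list[FeatureSchema]

    def __post_init__(self):
        self._schema = {s.name: s for s in self.schemas}

    @property
    def variant(self) -> str:
        kinds = {s.kind for s in self.schemas}
        if kinds == {"categorical"}:
            return "discrete"
        if kinds == {"continuous"}:
            return "gaussian"
        return "clg"

    def schema_of(self, name: str) -> FeatureSchema:
        return self._schema[name]

    # -- JSON round-trip for fixtures ----------------------------------
    def to_dict(self) -> dict:
        nodes = {}
        for name, cpd in self.cpds.items():
            if isinstance(cpd, DiscreteCpd):
                nodes[name] = {
                    "type": "discrete",
                    "levels": list(cpd.levels),
                    "parents": list(cpd.parents),
                    "table": {"|".join(k): list(map(float, v)) for k, v in cpd.table.items()},
                    "fallback": ["|".join(k) for k in cpd.fallback_configs],
                }
            else:
                nodes[name] = {
                    "type": "lg",
                    "disc_parents": list(cpd.disc_parents),
                    "cont_parents": list(cpd.cont_parents),
                    "params": {
                        "|".join(k): [float(b0), list(map(float, cf)), float(sd)]
                        for k, (b0, cf, sd) in cpd.params.items()
                    },
                    "fallback": ["|".join(k) for k in cpd.fallback_configs],
                }
        return {
            "nodes": [s.name for s in self.schemas],
            "schemas": [
                {"name": s.name, "kind": s.kind,
                 "levels": list(s.levels) if s.levels else None}
                for s in self.schemas
            ],
            "arcs": sorted(self.dag.arcs),
            "cpds": nodes,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BayesianNetwork":
        schemas = [
            FeatureSchema(d["name"], d["kind"], tuple(d["levels"]) if d["levels"] else None)
            for d in doc["schemas"]
        ]
        by_name = {s.name: s for s in schemas}
        dag = Dag(doc["nodes"], [tuple(a) for a in doc["arcs"]])
        cpds: dict = {}
        for name, nd in doc["cpds"].items():
            if nd["type"] == "discrete":
                parents = tuple(nd["parents"])
                cpds[name] = DiscreteCpd(
                    child=name,
                    levels=tuple(nd["levels"]),
                    parents=parents,
                    parent_levels=tuple(by_name[p].levels for p in parents),
                    table={tuple(k.split("|")) if k else (): np.asarray(v)
                           for k, v in nd["table"].items()},
                    fallback_configs=frozenset(
                        tuple(k.split("|")) if k else () for k in nd["fallback"]),
                )
            else:
                dp = tuple(nd["disc_parents"])
                cpds[name] = LinearGaussianCpd(
                    child=name,
                    disc_parents=dp,
                    disc_parent_levels=tuple(by_name[p].levels for p in dp),
                    cont_parents=tuple(nd["cont_parents"]),
                    params={tuple(k.split("|")) if k else (): (v[0], np.asarray(v[1]), v[2])
                            for k, v in nd["params"].items()},
                    fallback_configs=frozenset(
                        tuple(k.split("|")) if k else () for k in nd["fallback"]),
                )
        return cls(dag, cpds, schemas)


# ---------------------------------------------------------------------------
# MLE fitting


def _split_parents(dag: Dag, node: str, kinds: dict[str, str]):
    disc = tuple(p for p in dag.parents(node) if kinds[p] == "categorical")
    cont = tuple(p for p in dag.parents(node) if kinds[p] == "continuous")
    return disc, cont


def _sigma_floor(values: np.ndarray) -> float:
    return max(1e-6, 1e-3 * float(np.std(values)))


def _fit_discrete(df: pd.DataFrame, child: str, parents: tuple[str, ...],
                  levels: tuple[str, ...], parent_levels) -> DiscreteCpd:
    k = len(levels)
    lvl_idx = {l: i for i, l in enumerate(levels)}
    table: dict[tuple, np.ndarray] = {}
    fallback = set()
    if not parents:
        counts = np.zeros(k)
        vc = df[child].value_counts()
        for l, c in vc.items():
            counts[lvl_idx[l]] = c
        table[()] = counts / counts.sum()
    else:
        grouped: dict[tuple, np.ndarray] = {}
        gb = df.groupby(list(parents), observed=True)[child].value_counts()
        for key, c in gb.items():
            *cfg, lvl = key if isinstance(key, tuple) else (key,)
            cfg = tuple(cfg)
            grouped.setdefault(cfg, np.zeros(k))[lvl_idx[lvl]] += c
        for cfg in itertools.product(*parent_levels):
            if cfg in grouped:
                counts = grouped[cfg]
                table[cfg] = counts / counts.sum()
            else:
                table[cfg] = np.full(k, 1.0 / k)
                fallback.add(cfg)
    return DiscreteCpd(child, levels, parents, tuple(parent_levels), table,
                       frozenset(fallback))


def _lstsq_fit(y: np.ndarray, X: np.ndarray, floor: float):
    """Least squares of y on [1, X]; returns (b0, coefs, sd) or None if unusable."""
    n = len(y)
    if n < 2:
        return None
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    if n < A.shape[1] or np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sd = max(floor, math.sqrt(float(resid @ resid) / n))  # MLE variance
    return float(beta[0]), np.asarray(beta[1:], dtype=float), sd


def _fit_gaussian(df: pd.DataFrame, child: str, disc_parents, disc_parent_levels,
                  cont_parents) -> LinearGaussianCpd:
    y_all = df[child].to_numpy(dtype=float)
    floor = _sigma_floor(y_all)
    X_all = (df[list(cont_parents)].to_numpy(dtype=float)
             if cont_parents else np.empty((len(df), 0)))
    pooled = _lstsq_fit(y_all, X_all, floor)
    if pooled is None:
        pooled = (float(np.mean(y_all)), np.zeros(len(cont_parents)), floor)

    params: dict[tuple, tuple] = {}
    fallback = set()
    if not disc_parents:
        params[()] = pooled
    else:
        keys = df[list(disc_parents)].apply(tuple, axis=1)
        groups = {cfg: np.flatnonzero((keys == cfg).to_numpy())
                  for cfg in set(keys)}
        for cfg in itertools.product(*disc_parent_levels):
            idx = groups.get(cfg)
            fit = (_lstsq_fit(y_all[idx], X_all[idx], floor)
                   if idx is not None and len(idx) >= 2 else None)
            if fit is None:
                params[cfg] = pooled
                fallback.add(cfg)
            else:
                params[cfg] = fit
    return LinearGaussianCpd(child, tuple(disc_parents), tuple(disc_parent_levels),
                             tuple(cont_parents), params, frozenset(fallback))


def fit_mle(dag: Dag, df: pd.DataFrame, schemas: list[FeatureSchema]) -> BayesianNetwork:
    """Maximum-likelihood parameters for ``dag`` from ``df``.

    Discrete CPT entries are empirical conditional frequencies; unseen parent
    configurations get a flagged uniform fallback.  Linear-Gaussian families
    are per-configuration least squares with MLE (divide-by-n) variance,
    floored at ``max(1e-6, 1e-3·sd(child))``; degenerate configurations fall
    back to the pooled fit with a warning.
    """
    if df.empty:
        raise FitError("cannot fit a Bayesian network on an empty table")
    kinds = {s.name: s.kind for s in schemas}
    by_name = {s.name: s for s in schemas}
    if set(df.columns) != set(kinds):
        raise PreconditionError("data columns do not match the DAG's nodes")
    cpds: dict = {}
    for node in dag.nodes:
        s = by_name[node]
        disc, cont = _split_parents(dag, node, kinds)
        if s.is_categorical:
            if cont:
                raise PreconditionError(f"categorical node {node!r} has a continuous parent")
            cpds[node] = _fit_discrete(df, node, disc,
                                       s.levels, tuple(by_name[p].levels for p in disc))
        else:
            cpd = _fit_gaussian(df, node, disc,
                                tuple(by_name[p].levels for p in disc), cont)
            if cpd.fallback_configs and disc:
                warnings.warn(
                    f"node {node!r}: {len(cpd.fallback_configs)} parent configuration(s) "
                    "had too little data; pooled fit used", stacklevel=2)
            cpds[node] = cpd
    return BayesianNetwork(dag, cpds, [by_name[n] for n in dag.nodes])


# ---------------------------------------------------------------------------
# Log-likelihood scoring (decomposable)


def family_log_likelihood(df: pd.DataFrame, child: str, parents: tuple[str, ...],
                          schemas: list[FeatureSchema]) -> float:
    """Log-likelihood contribution of one node family under its MLE fit."""
    by_name = {s.name: s for s in schemas}
    kinds = {s.name: s.kind for s in schemas}
    s = by_name[child]
    if s.is_categorical:
        # sum n(c,pa) log n(c,pa) - sum n(pa) log n(pa)
        if any(kinds[p] == "continuous" for p in parents):
            raise PreconditionError(f"categorical node {child!r} has a continuous parent")
        joint = df.groupby(list(parents) + [child], observed=True).size().to_numpy(dtype=float)
        ll = float(np.sum(joint * np.log(joint)))
        if parents:
            marg = df.groupby(list(parents), observed=True).size().to_numpy(dtype=float)
            ll -= float(np.sum(marg * np.log(marg)))
        else:
            ll -= len(df) * math.log(len(df))
        return ll
    disc = tuple(p for p in parents if kinds[p] == "categorical")
    cont = tuple(p for p in parents if kinds[p] == "continuous")
    cpd = _fit_gaussian(df, child, disc, tuple(by_name[p].levels for p in disc), cont)
    y = df[child].to_numpy(dtype=float)
    X = df[list(cont)].to_numpy(dtype=float) if cont else np.empty((len(df), 0))
    if disc:
        keys = df[list(disc)].apply(tuple, axis=1).to_numpy()
    ll = 0.0
    for i in range(len(df)):
        cfg = tuple(keys[i]) if disc else ()
        b0, coefs, sd = cpd.params[cfg]
        z = (y[i] - b0 - (coefs @ X[i] if cont else 0.0)) / sd
        ll += -0.5 * (LOG_2PI + z * z) - math.log(sd)
    return ll


def log_likelihood_score(dag: Dag, df: pd.DataFrame,
                         schemas: list[FeatureSchema]) -> float:
    """Fitted log-likelihood of ``df`` under ``dag`` (sum of family terms)."""
    if df.empty:
        raise FitError("empty data")
    return sum(family_log_likelihood(df, node, dag.parents(node), schemas)
               for node in dag.nodes)


# ---------------------------------------------------------------------------
# Hill climbing


@dataclass
class LearnConfig:
    """Knobs of the structure search (the underlying method leaves them open).

    epsilon
        minimum strict score gain to accept a move (log-likelihood units).
    max_parents
        parent cap per node; ``None`` = unbounded.
    max_iter
        cap on accepted moves; exceeded ⇒ best-so-far with a warning.
    """

    epsilon: float = 1e-6
    max_parents: int | None = None
    max_iter: int = 1000

    def __post_init__(self):
        if self.epsilon <= 0 or self.max_iter <= 0:
            raise PreconditionError("epsilon and max_iter must be positive")


_MOVE_RANK = {"add": 0, "remove": 1, "reverse": 2}


def hill_climb(df: pd.DataFrame, schemas: list[FeatureSchema],
               config: LearnConfig | None = None) -> Dag:
    """Steepest-ascent structure search from the empty graph.

    Every legal single-arc addition, removal and reversal is scored
    (acyclicity, the CLG no-continuous-parent-of-categorical rule and the
    parent cap filtered out); the best move is applied iff its gain exceeds
    ``epsilon``.  Ties break on move type (add < remove < reverse) then
    lexicographically on (parent, child), so the result is deterministic.
    """
    config = config or LearnConfig()
    if len(df) < 2:
        raise FitError("hill climbing needs at least 2 rows")
    kinds = {s.name: s.kind for s in schemas}
    nodes = [s.name for s in schemas]
    dag = Dag(nodes)
    cache: dict[tuple[str, frozenset], float] = {}

    def fam(child: str, parents: tuple[str, ...]) -> float:
        key = (child, frozenset(parents))
        if key not in cache:
            cache[key] = family_log_likelihood(df, child, parents, schemas)
        return cache[key]

    def legal_parent(p: str, c: str) -> bool:
        return not (kinds[c] == "categorical" and kinds[p] == "continuous")

    current = {n: fam(n, ()) for n in nodes}

    for _ in range(config.max_iter):
        best = None  # (gain, rank, parent, child, apply)
        for p, c in itertools.permutations(nodes, 2):
            pc = dag.parents(c)
            if not dag.has_arc(p, c):
                # addition
                if (legal_parent(p, c) and dag.would_be_acyclic(p, c)
                        and (config.max_parents is None or len(pc) < config.max_parents)):
                    gain = fam(c, pc + (p,)) - current[c]
                    cand = (gain, _MOVE_RANK["add"], p, c)
                    if best is None or _better(cand, best):
                        best = cand + (("add", p, c),)
            else:
                # removal
                gain = fam(c, tuple(x for x in pc if x != p)) - current[c]
                cand = (gain, _MOVE_RANK["remove"], p, c)
                if best is None or _better(cand, best):
                    best = cand + (("remove", p, c),)
                # reversal p->c  ==>  c->p
                dag.remove_arc(p, c)
                ok = (legal_parent(c, p) and dag.would_be_acyclic(c, p)
                      and (config.max_parents is None
                           or len(dag.parents(p)) < config.max_parents))
                dag.add_arc(p, c)
                if ok:
                    new_pc = tuple(x for x in pc if x != p)
                    new_pp = dag.parents(p) + (c,)
                    gain = (fam(c, new_pc) - current[c]) + (fam(p, new_pp) - current[p])
                    cand = (gain, _MOVE_RANK["reverse"], p, c)
                    if best is None or _better(cand, best):
                        best = cand + (("reverse", p, c),)
        if best is None or best[0] <= config.epsilon:
            return dag
        _, _, _, _, (kind, p, c) = best
        if kind == "add":
            dag.add_arc(p, c)
        elif kind == "remove":
            dag.remove_arc(p, c)
        else:
            dag.remove_arc(p, c)
            dag.add_arc(c, p)
        for n in ((c,) if kind != "reverse" else (p, c)):
            current[n] = fam(n, dag.parents(n))
    warnings.warn("hill_climb: max_iter reached; returning best-so-far structure",
                  stacklevel=2)
    return dag


def _better(cand, best) -> bool:
    """Higher gain wins; then add < remove < reverse; then (parent, child)."""
    return (-cand[0], cand[1], cand[2], cand[3]) < (-best[0], best[1], best[2], best[3])


# ---------------------------------------------------------------------------
# Sampling and the chain-rule joint


def logic_sample(bn: BayesianNetwork, n: int, seed=None) -> pd.DataFrame:
    """Forward-sample ``n`` complete rows in topological order.

    Each node is drawn from its conditional distribution given the
    already-sampled parent values; flagged fallback configurations use the
    uniform (discrete) or pooled (Gaussian) distribution.  A fixed seed gives
    identical output.
    """
    if n < 0:
        raise PreconditionError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    order = topological_order(bn.dag)
    for node in order:
        cpd = bn.cpds[node]
        if isinstance(cpd, DiscreteCpd):
            levels = np.asarray(cpd.levels, dtype=object)
            out = np.empty(n, dtype=object)
            if not cpd.parents:
                idx = rng.choice(len(levels), size=n, p=cpd.table[()])
                out[:] = levels[idx]
            else:
                keys = list(zip(*(cols[p] for p in cpd.parents))) if n else []
                groups: dict[tuple, list[int]] = {}
                for i, kv in enumerate(keys):
                    groups.setdefault(kv, []).append(i)
                for cfg in sorted(groups):
                    rows = groups[cfg]
                    idx = rng.choice(len(levels), size=len(rows), p=cpd.table[cfg])
                    out[rows] = levels[idx]
            cols[node] = out
        else:
            out = np.empty(n, dtype=float)
            cont_vals = (np.column_stack([cols[p] for p in cpd.cont_parents]).astype(float)
                         if cpd.cont_parents and n else np.empty((n, 0)))
            if not cpd.disc_parents:
                groups = {(): list(range(n))}
            else:
                keys = list(zip(*(cols[p] for p in cpd.disc_parents))) if n else []
                groups = {}
                for i, kv in enumerate(keys):
                    groups.setdefault(kv, []).append(i)
            for cfg in sorted(groups):
                rows = np.asarray(groups[cfg], dtype=int)
                b0, coefs, sd = cpd.params[cfg]
                mu = b0 + (cont_vals[rows] @ coefs if len(coefs) else 0.0)
                out[rows] = mu + sd * rng.standard_normal(len(rows))
            cols[node] = out
    names = [s.name for s in bn.schemas]
    return pd.DataFrame({name: cols[name] if n else
                         pd.Series(dtype=object if bn.schema_of(name).is_categorical else float)
                         for name in names})


def joint_probability(bn: BayesianNetwork, instance: dict) -> float:
    """Chain-rule joint probability (a density if continuous nodes exist)."""
    log_p = 0.0
    for node in bn.dag.nodes:
        cpd = bn.cpds[node]
        if isinstance(cpd, DiscreteCpd):
            val = str(instance[node])
            if val not in cpd.levels:
                raise PreconditionError(f"value {val!r} outside levels of {node!r}")
            cfg = tuple(str(instance[p]) for p in cpd.parents)
            p = cpd.prob(val, cfg)
            if p == 0.0:
                return 0.0
            log_p += math.log(p)
        else:
            cfg = tuple(str(instance[p]) for p in cpd.disc_parents)
            cont = np.asarray([float(instance[p]) for p in cpd.cont_parents])
            log_p += cpd.logpdf(float(instance[node]), cfg, cont)
    return math.exp(log_p)


def enumerate_joint(bn: BayesianNetwork) -> dict[tuple, float]:
    """All-configuration joint of a fully discrete network (small nets only)."""
    if bn.variant != "discrete":
        raise PreconditionError("enumeration requires a fully discrete network")
    names = [s.name for s in bn.schemas]
    levels = [bn.schema_of(n).levels for n in names]
    return {
        cfg: joint_probability(bn, dict(zip(names, cfg)))
        for cfg in itertools.product(*levels)
    }


# ---------------------------------------------------------------------------
# sklearn-style estimator


class BayesianNetworkSampler:
    """Estimator facade: learn structure + parameters, then sample or score.

    Parameters mirror :class:`LearnConfig`.  After ``fit``, the learned graph
    is in ``dag_`` and the parameterized network in ``network_``.
    """

    def __init__(self, epsilon: float = 1e-6, max_parents: int | None = None,
                 max_iter: int = 1000):
        self.epsilon = epsilon
        self.max_parents = max_parents
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"epsilon": self.epsilon, "max_parents": self.max_parents,
                "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None, schemas: list[FeatureSchema] | None = None):
        from .data_model import infer_schema

        self.schemas_ = schemas if schemas is not None else infer_schema(X)
        cfg = LearnConfig(epsilon=self.epsilon, max_parents=self.max_parents,
                          max_iter=self.max_iter)
        self.dag_ = hill_climb(X, self.schemas_, cfg)
        self.network_ = fit_mle(self.dag_, X, self.schemas_)
        return self

    def sample(self, n: int, seed=None) -> pd.DataFrame:
        return logic_sample(self.network_, n, seed=seed)

    def score(self, X: pd.DataFrame) -> float:
        return log_likelihood_score(self.dag_, X, self.schemas_)
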