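"""Two-stage experimental pipeline for comparing over-samplers.

Stage 1: repeated stratified k-fold cross-validation where over-sampling is
applied to the training folds only (with the cost-derived target proportion
q), classifiers are learned on the enlarged folds, and accuracy plus
expected misclassification cost are measured on the untouched validation
folds.  Stage 2: per run, the two accuracy vectors of a method pair are
compared with a Shapiro–Wilk-gated paired test (t-test if normality of the
differences is tenable, Wilcoxon signed-rank otherwise); wins are tallied in
counters, summarized by exact-binomial point probabilities and β-scores, and
the β-score-vs-γ series is examined for monotone trend (Mann–Kendall with
Sen's slope, and Spearman rank correlation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .costsense import CostSpec, expected_cost, target_q
from .data_model import DatasetTable, PreconditionError, class_balance

__all__ = [
    "EvalConfig", "FoldScores", "ComparisonVerdict", "CounterLedger", "TrendResult",
    "kfold_indices", "run_cv_experiment", "paired_compare", "count_wins",
    "binomial_point_p", "beta_score", "mann_kendall_trend", "spearman_trend",
    "MixedNaiveBayes",
]


@dataclass
class EvalConfig:
    k: int = 10
    runs: int = 10
    alpha: float = 0.05
    gamma_grid: tuple = tuple(range(5, 55, 5))
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.runs < 1 or not 0 < self.alpha < 1:
            raise PreconditionError("invalid evaluation configuration")
        if any(g <= 1 for g in self.gamma_grid):
            raise PreconditionError("gamma grid values must exceed 1")


@dataclass
class FoldScores:
    """Per-fold accuracy and expected-cost vectors for one (run, method, classifier)."""

    method: str
    classifier: str
    run: int
    accuracies: np.ndarray
    expected_costs: np.ndarray
    seeds: dict = field(default_factory=dict)


@dataclass
class ComparisonVerdict:
    normality_p: float | None
    test_used: str  # paired_t | wilcoxon | degenerate
    test_p: float | None
    direction: str  # first | second | none
    significant: bool


@dataclass
class CounterLedger:
    """Wins of the first method (counter+) and the comparator (counter−)."""

    counter_plus: int
    counter_minus: int
    context: tuple = ()


@dataclass
class TrendResult:
    S: int | None = None
    var_S: float | None = None
    tau: float | None = None
    p_two_sided: float | None = None
    sen_slope: float | None = None
    sen_ci: tuple[float, float] | None = None
    rho: float | None = None
    rho_p_one_sided: float | None = None


# ---------------------------------------------------------------------------
# Folds


def kfold_indices(n_rows: int, k: int, seed=None, stratified: bool = False,
                  labels=None) -> list[np.ndarray]:
    """Seeded k-fold partition; fold sizes differ by ≤ 1.

    Stratified folds additionally keep per-fold minority counts within 1 of
    each other (labels required).
    """
    if k > n_rows:
        raise PreconditionError(f"k={k} exceeds the number of rows {n_rows}")
    if stratified:
        if labels is None:
            raise PreconditionError("stratified folds require labels")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n_rows), np.asarray(labels))]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n_rows))]


# ---------------------------------------------------------------------------
# Reference classifier (naive Bayes over mixed features)


class MixedNaiveBayes:
    """Naive Bayes over mixed features: categorical via add-one-smoothed
    frequencies, continuous via per-class Gaussians (MLE variance, floored sd).

    Ships in-repo so the harness and its tests need no heavyweight model
    dependency; ties in the posterior go to the first class in sorted order.
    """

    def __init__(self, laplace: float = 1.0):
        self.laplace = laplace

    def get_params(self, deep: bool = True) -> dict:
        return {"laplace": self.laplace}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(map(str, y))), dtype=object)
        y = np.array([str(v) for v in y], dtype=object)
        self.priors_ = {c: np.mean(y == c) for c in self.classes_}
        self.cat_cols_ = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
        self.num_cols_ = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
        self.cat_params_: dict = {}
        self.num_params_: dict = {}
        for col in self.cat_cols_:
            levels = sorted(map(str, pd.unique(X[col].astype(str))))
            per_class = {}
            for c in self.classes_:
                vals = X[col].astype(str).to_numpy()[y == c]
                counts = {l: self.laplace for l in levels}
                for v in vals:
                    counts[v] = counts.get(v, self.laplace) + 1
                total = sum(counts.values())
                per_class[c] = {l: cnt / total for l, cnt in counts.items()}
            self.cat_params_[col] = (levels, per_class)
        for col in self.num_cols_:
            v_all = X[col].to_numpy(dtype=float)
            floor = max(1e-6, 1e-3 * float(np.std(v_all)))
            per_class = {}
            for c in self.classes_:
                v = v_all[y == c]
                mu = float(np.mean(v)) if len(v) else 0.0
                sd = max(floor, float(np.std(v))) if len(v) else floor
                per_class[c] = (mu, sd)
            self.num_params_[col] = per_class
        return self

    def _log_posteriors(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        out = np.zeros((n, len(self.classes_)))
        for j, c in enumerate(self.classes_):
            out[:, j] = math.log(self.priors_[c]) if self.priors_[c] > 0 else -np.inf
            for col in self.cat_cols_:
                levels, per_class = self.cat_params_[col]
                probs = per_class[c]
                unseen = self.laplace / (sum(self.laplace for _ in levels) + 1)
                vals = X[col].astype(str).to_numpy()
                out[:, j] += np.array([math.log(probs.get(v, unseen)) for v in vals])
            for col in self.num_cols_:
                mu, sd = self.num_params_[col][c]
                v = X[col].to_numpy(dtype=float)
                out[:, j] += -0.5 * ((v - mu) / sd) ** 2 - math.log(sd)
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        lp = self._log_posteriors(X)
        return self.classes_[np.argmax(lp, axis=1)]


# ---------------------------------------------------------------------------
# Stage 1: cross-validated experiment


def _clone(est):
    return type(est)(**est.get_params())


def run_cv_experiment(
    table: DatasetTable,
    minority_label: str,
    oversamplers: dict,
    classifiers: dict,
    costs: CostSpec,
    config: EvalConfig,
) -> list[FoldScores]:
    """Repeated k-fold CV with over-sampling inside the training folds.

    ``oversamplers`` maps a method name to a callable
    ``fn(table, minority_label, q, seed) -> DatasetTable`` or ``None`` for no
    over-sampling; ``classifiers`` maps a name to an unfitted estimator with
    ``fit(X, y)`` / ``predict(X)``.  For every run and fold the target
    proportion q is derived from the training fold's class balance and the
    costs; accuracy and expected cost are measured on the untouched
    validation fold.  All seeds derive from ``config.seed`` via a fixed
    splitting rule and are recorded in each result's seed ledger.
    """
    table.validate()
    n = table.n_rows
    y_all = table.df[table.class_name].to_numpy()
    results: dict[tuple, FoldScores] = {}
    master = np.random.SeedSequence(config.seed)
    run_seqs = master.spawn(config.runs)
    method_names = list(oversamplers)

    for run, seq in enumerate(run_seqs):
        state = seq.generate_state(2)
        fold_seed = int(state[0] % (2 ** 31))
        os_base = int(state[1] % (2 ** 31))
        folds = kfold_indices(n, config.k, seed=fold_seed,
                              stratified=config.stratified,
                              labels=y_all if config.stratified else None)
        for key in ((run, m, c) for m in method_names for c in classifiers):
            results[key] = FoldScores(
                method=key[1], classifier=key[2], run=run,
                accuracies=np.full(config.k, np.nan),
                expected_costs=np.full(config.k, np.nan),
                seeds={"fold_seed": fold_seed, "oversample_base": os_base},
            )
        for fi, val_idx in enumerate(folds):
            mask = np.zeros(n, dtype=bool)
            mask[val_idx] = True
            train = table.subset(~mask)
            val = table.subset(mask)
            try:
                balance = class_balance(train, minority_label)
                if balance.m_plus < 2:
                    raise PreconditionError("fewer than 2 minority rows")
            except PreconditionError as exc:
                warnings.warn(f"run {run} fold {fi} skipped: {exc}", stacklevel=2)
                continue
            q = target_q(balance, costs)
            y_val = val.df[val.class_name].to_numpy()
            X_val = val.X
            for mi, (method, fn) in enumerate(oversamplers.items()):
                os_seed = (os_base + 1000 * fi + mi) % (2 ** 31)
                enlarged = train if fn is None else fn(train, minority_label, q, os_seed)
                X_tr, y_tr = enlarged.X, enlarged.df[enlarged.class_name].to_numpy()
                for cname, proto in classifiers.items():
                    clf = _clone(proto)
                    clf.fit(X_tr, y_tr)
                    pred = np.asarray(clf.predict(X_val), dtype=object)
                    acc = float(np.mean(pred == y_val))
                    conf = {
                        "TP": int(np.sum((pred == minority_label) & (y_val == minority_label))),
                        "FP": int(np.sum((pred == minority_label) & (y_val != minority_label))),
                        "TN": int(np.sum((pred != minority_label) & (y_val != minority_label))),
                        "FN": int(np.sum((pred != minority_label) & (y_val == minority_label))),
                    }
                    fs = results[(run, method, cname)]
                    fs.accuracies[fi] = acc
                    fs.expected_costs[fi] = expected_cost(conf, costs)
    return list(results.values())


# ---------------------------------------------------------------------------
# Stage 2: paired comparison and counters


def paired_compare(x, y, alpha: float = 0.05) -> ComparisonVerdict:
    """Shapiro–Wilk-gated paired test on d = x − y.

    If normality of d is rejected (Shapiro p < 0.05) a Wilcoxon signed-rank
    test is used (zeros dropped; exact p when n ≤ 25 with untied |d| ranks,
    else a continuity-corrected normal approximation); otherwise a paired
    t-test.  Direction follows the mean (t branch) or median (Wilcoxon
    branch) of d.  All-zero differences give a non-significant degenerate
    verdict; constant nonzero differences a degenerate-significant one.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(d) < 3:
        raise PreconditionError("paired comparison needs at least 3 pairs")
    if np.all(d == 0):
        return ComparisonVerdict(None, "degenerate", None, "none", False)
    if np.ptp(d) == 0:  # constant nonzero
        direction = "first" if d[0] > 0 else "second"
        return ComparisonVerdict(None, "degenerate", None, direction, True)

    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p < 0.05:
        dz = d[d != 0]
        ranks_tied = len(np.unique(np.abs(dz))) < len(dz)
        method = "approx" if (len(dz) > 25 or ranks_tied) else "exact"
        res = stats.wilcoxon(dz, correction=True, method=method)
        p = float(res.pvalue)
        center = float(np.median(d))
        if center == 0:
            center = float(np.mean(d))
        test_used = "wilcoxon"
    else:
        res = stats.ttest_rel(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        p = float(res.pvalue)
        center = float(np.mean(d))
        test_used = "paired_t"
    direction = "first" if center > 0 else ("second" if center < 0 else "none")
    significant = bool(p < alpha and direction != "none")
    return ComparisonVerdict(sw_p, test_used, p, direction, significant)


def count_wins(results: list[FoldScores], method_a: str, method_b: str,
               classifier: str, alpha: float = 0.05,
               metric: str = "accuracies", context: tuple = ()) -> CounterLedger:
    """Tally runs in which ``method_a`` (counter+) or ``method_b`` (counter−)
    is significantly better on the per-fold score vectors."""
    runs = sorted({r.run for r in results})
    cp = cm = 0
    by_key = {(r.run, r.method, r.classifier): r for r in results}
    for run in runs:
        a = by_key[(run, method_a, classifier)]
        b = by_key[(run, method_b, classifier)]
        xa, xb = getattr(a, metric), getattr(b, metric)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < 3:
            continue
        verdict = paired_compare(xa[ok], xb[ok], alpha=alpha)
        if verdict.significant:
            if verdict.direction == "first":
                cp += 1
            else:
                cm += 1
    return CounterLedger(cp, cm, context=context)


def binomial_point_p(counter_plus: int, counter_minus: int) -> float:
    """Exact point mass P(B(n, 1/2) = counter+), n = counter+ + counter−.

    Computed in exact rational arithmetic before conversion to float.
    """
    if counter_plus < 0 or counter_minus < 0:
        raise PreconditionError("counters must be non-negative")
    n = counter_plus + counter_minus
    if n == 0:
        raise PreconditionError("both counters are zero")
    return float(Fraction(math.comb(n, counter_plus), 2 ** n))


def beta_score(verdicts) -> int:
    """Sum of per-cell verdicts (+1 favors the method, −1 the comparator, 0 none)."""
    total = 0
    for v in verdicts:
        if v not in (-1, 0, 1):
            raise PreconditionError(f"verdict {v!r} not in {{-1, 0, +1}}")
        total += v
    return total


# ---------------------------------------------------------------------------
# Trend statistics


def mann_kendall_trend(series) -> TrendResult:
    """Mann–Kendall monotone-trend test with tie correction and Sen's slope.

    S = Σ_{i<j} sign(y_j − y_i); var(S) is tie-corrected; the two-sided p
    uses a continuity-corrected normal approximation; tau is tau-b.  Sen's
    slope is the median pairwise slope per index step, with a 95% CI from
    the rank-based normal approximation.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 4:
        raise PreconditionError("trend test needs at least 4 values")
    S = 0
    slopes = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            S += int(np.sign(y[j] - y[i]))
            slopes.append((y[j] - y[i]) / (j - i))
    _, counts = np.unique(y, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    pairs = n * (n - 1) / 2
    d2 = pairs - float(np.sum(counts * (counts - 1))) / 2
    tau = S / math.sqrt(pairs * d2) if d2 > 0 else 0.0

    if var_S > 0 and S != 0:
        z = (S - np.sign(S)) / math.sqrt(var_S)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        p = 1.0
    slopes = np.sort(np.asarray(slopes))
    sen = float(np.median(slopes))
    Np = len(slopes)
    C = stats.norm.ppf(0.975) * math.sqrt(var_S) if var_S > 0 else 0.0
    lo_idx = int(np.clip(math.floor((Np - C) / 2), 0, Np - 1))
    hi_idx = int(np.clip(math.ceil((Np + C) / 2), 0, Np - 1))
    lo = min(float(slopes[lo_idx]), sen)
    hi = max(float(slopes[hi_idx]), sen)
    return TrendResult(S=S, var_S=var_S, tau=tau, p_two_sided=min(p, 1.0),
                       sen_slope=sen, sen_ci=(lo, hi))


def spearman_trend(series) -> TrendResult:
    """Spearman rank correlation of the series against its index order,
    with a one-sided p-value for the alternative ρ > 0 (t approximation)."""
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 4:
        raise PreconditionError("trend test needs at least 4 values")
    if np.ptp(y) == 0:
        raise PreconditionError("series has zero rank variance")
    rho, p = stats.spearmanr(np.arange(1, n + 1), y, alternative="greater")
    return TrendResult(rho=float(rho), rho_p_one_sided=float(p))
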