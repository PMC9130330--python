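import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bosme.bayesnet import (
    BayesianNetwork,
    BayesianNetworkSampler,
    CycleError,
    Dag,
    DiscreteCpd,
    FitError,
    LearnConfig,
    enumerate_joint,
    family_log_likelihood,
    fit_mle,
    hill_climb,
    joint_probability,
    log_likelihood_score,
    logic_sample,
    topological_order,
)
from bosme.data_model import FeatureSchema

from conftest import all_three_node_dags, exhaustive_best_score

AB = [FeatureSchema("A", "categorical", ("0", "1")),
      FeatureSchema("B", "categorical", ("0", "1"))]


def naive_loglik(dag, df, schemas):
    """Independent oracle: fit CPTs by raw counting, evaluate row by row."""
    total = 0.0
    for node in dag.nodes:
        parents = dag.parents(node)
        for _, row in df.iterrows():
            cfg = tuple(row[p] for p in parents)
            sub = df
            for p, v in zip(parents, cfg):
                sub = sub[sub[p] == v]
            p_val = (sub[node] == row[node]).mean()
            total += math.log(p_val)
    return total


class TestDag:
    def test_chain_topological_order(self):
        d = Dag(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert topological_order(d) == ["A", "B", "C"]

    def test_declaration_order_without_arcs(self):
        assert topological_order(Dag(["X2", "X1"])) == ["X2", "X1"]

    def test_cycle_rejected_on_mutation(self):
        d = Dag(["A", "B"], [("A", "B")])
        with pytest.raises(CycleError):
            d.add_arc("B", "A")

    def test_self_loop_rejected(self):
        with pytest.raises(CycleError):
            Dag(["A"], [("A", "A")])

    def test_parents_recoverable(self):
        d = Dag(["A", "B", "C"], [("A", "C"), ("B", "C")])
        assert d.parents("C") == ("A", "B")


class TestFitMle:
    def test_single_node_frequencies(self):
        df = pd.DataFrame({"A": ["a", "a", "a", "b"]})
        sch = [FeatureSchema("A", "categorical", ("a", "b"))]
        bn = fit_mle(Dag(["A"]), df, sch)
        assert bn.cpds["A"].table[()] == pytest.approx([0.75, 0.25])

    def test_conditional_frequencies(self):
        df = pd.DataFrame({"A": ["0", "0", "0", "1"], "B": ["0", "0", "1", "1"]})
        bn = fit_mle(Dag(["A", "B"], [("A", "B")]), df, AB)
        cpd = bn.cpds["B"]
        assert cpd.prob("0", ("0",)) == pytest.approx(2 / 3)
        assert cpd.prob("1", ("1",)) == pytest.approx(1.0)

    def test_constant_column_degenerate(self):
        df = pd.DataFrame({"A": ["a", "a", "a"]})
        sch = [FeatureSchema("A", "categorical", ("a", "b"))]
        bn = fit_mle(Dag(["A"]), df, sch)
        assert bn.cpds["A"].table[()] == pytest.approx([1.0, 0.0])

    def test_unseen_parent_config_uniform_and_flagged(self):
        df = pd.DataFrame({"A": ["0", "0", "0"], "B": ["0", "1", "0"]})
        bn = fit_mle(Dag(["A", "B"], [("A", "B")]), df, AB)
        cpd = bn.cpds["B"]
        assert ("1",) in cpd.fallback_configs
        assert cpd.table[("1",)] == pytest.approx([0.5, 0.5])

    def test_empty_data_errors(self):
        with pytest.raises(FitError):
            fit_mle(Dag(["A"]), pd.DataFrame({"A": []}), AB[:1])

    def test_cpt_rows_normalized(self, discrete_problem):
        _, bn_pos, _, table = discrete_problem
        minority = table.df[table.df["V"] == "+"][[s.name for s in bn_pos.schemas]]
        bn = fit_mle(hill_climb(minority, list(bn_pos.schemas)), minority,
                     list(bn_pos.schemas))
        for cpd in bn.cpds.values():
            for vec in cpd.table.values():
                assert vec.sum() == pytest.approx(1.0, abs=1e-12)
                assert (vec >= 0).all()

    def test_gaussian_fit_recovers_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = 2.0 + 3.0 * x + 0.1 * rng.normal(size=400)
        df = pd.DataFrame({"X": x, "Y": y})
        sch = [FeatureSchema("X", "continuous"), FeatureSchema("Y", "continuous")]
        bn = fit_mle(Dag(["X", "Y"], [("X", "Y")]), df, sch)
        b0, coefs, sd = bn.cpds["Y"].params[()]
        assert b0 == pytest.approx(2.0, abs=0.05)
        assert coefs[0] == pytest.approx(3.0, abs=0.05)
        assert 0 < sd < 0.15

    def test_clg_config_with_too_few_rows_pools(self):
        df = pd.DataFrame({"G": ["a", "a", "a", "b"], "Y": [1.0, 2.0, 3.0, 9.0]})
        sch = [FeatureSchema("G", "categorical", ("a", "b")),
               FeatureSchema("Y", "continuous")]
        with pytest.warns(UserWarning, match="pooled"):
            bn = fit_mle(Dag(["G", "Y"], [("G", "Y")]), df, sch)
        assert ("b",) in bn.cpds["Y"].fallback_configs


class TestScore:
    def test_closed_form_single_node(self):
        df = pd.DataFrame({"A": ["a", "a", "a", "b"]})
        sch = [FeatureSchema("A", "categorical", ("a", "b"))]
        score = log_likelihood_score(Dag(["A"]), df, sch)
        assert score == pytest.approx(3 * math.log(0.75) + math.log(0.25), abs=1e-12)

    def test_deterministic_copy_family_is_zero(self):
        df = pd.DataFrame({"A": ["0", "1", "0", "1"], "B": ["0", "1", "0", "1"]})
        assert family_log_likelihood(df, "B", ("A",), AB) == pytest.approx(0.0, abs=1e-12)

    def test_decomposability_against_naive_oracle(self):
        rng = np.random.default_rng(5)
        sch = [FeatureSchema(n, "categorical", ("0", "1")) for n in "ABC"]
        df = pd.DataFrame({n: rng.choice(["0", "1"], size=40) for n in "ABC"})
        dag = Dag(["A", "B", "C"], [("A", "B"), ("A", "C")])
        assert log_likelihood_score(dag, df, sch) == pytest.approx(
            naive_loglik(dag, df, sch), abs=1e-9)
        # and it equals the sum of independently recomputed family terms
        total = sum(family_log_likelihood(df, n, dag.parents(n), sch) for n in "ABC")
        assert log_likelihood_score(dag, df, sch) == pytest.approx(total, abs=1e-9)

    def test_arc_addition_never_decreases_fitted_loglik(self):
        rng = np.random.default_rng(11)
        sch = [FeatureSchema(n, "categorical", ("0", "1")) for n in "ABC"]
        df = pd.DataFrame({n: rng.choice(["0", "1"], size=30) for n in "ABC"})
        empty = log_likelihood_score(Dag(["A", "B", "C"]), df, sch)
        for p, c in itertools.permutations("ABC", 2):
            one = log_likelihood_score(Dag(["A", "B", "C"], [(p, c)]), df, sch)
            assert one >= empty - 1e-9

    def test_mle_is_optimal_under_cpt_perturbation(self):
        """Perturbing fitted CPT rows (renormalized) never increases the data
        log-likelihood — the defining property of the MLE."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"A": rng.choice(["0", "1"], size=50, p=[0.7, 0.3]),
                           "B": rng.choice(["0", "1"], size=50)})
        dag = Dag(["A", "B"], [("A", "B")])
        bn = fit_mle(dag, df, AB)
        base = log_likelihood_score(dag, df, AB)

        def loglik_under(bn_mod):
            return sum(math.log(joint_probability(
                bn_mod, {"A": r.A, "B": r.B})) for r in df.itertuples())

        assert loglik_under(bn) == pytest.approx(base, abs=1e-9)
        for _ in range(20):
            import copy
            mod = copy.deepcopy(bn)
            cpd = mod.cpds[rng.choice(["A", "B"])]
            cfg = list(cpd.table)[rng.integers(len(cpd.table))]
            vec = cpd.table[cfg] + rng.uniform(0.01, 0.2, size=2)
            cpd.table[cfg] = vec / vec.sum()
            assert loglik_under(mod) <= base + 1e-9


class TestHillClimb:
    def test_empirical_independence_gives_empty_graph(self):
        df = pd.DataFrame({"A": ["0", "0", "1", "1"], "B": ["0", "1", "0", "1"]})
        assert hill_climb(df, AB).arcs == set()

    def test_perfect_dependence_single_arc_lexicographic(self):
        df = pd.DataFrame({"A": ["0", "0", "1", "1"], "B": ["0", "0", "1", "1"]})
        dag = hill_climb(df, AB)
        assert dag.arcs == {("A", "B")}  # tie with B->A broken lexicographically
        gain = (log_likelihood_score(dag, df, AB)
                - log_likelihood_score(Dag(["A", "B"]), df, AB))
        assert gain == pytest.approx(4 * math.log(2), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beats_exhaustive_three_node_search(self, seed):
        rng = np.random.default_rng(seed)
        sch = [FeatureSchema(n, "categorical", ("0", "1")) for n in "ABC"]
        df = pd.DataFrame({n: rng.choice(["0", "1"], size=50) for n in "ABC"})
        hc = log_likelihood_score(hill_climb(df, sch), df, sch)
        assert hc <= exhaustive_best_score(df, sch) + 1e-9

    def test_local_optimum_certificate(self):
        rng = np.random.default_rng(8)
        sch = [FeatureSchema(n, "categorical", ("0", "1")) for n in "ABC"]
        df = pd.DataFrame({n: rng.choice(["0", "1"], size=60) for n in "ABC"})
        cfg = LearnConfig()
        dag = hill_climb(df, sch, cfg)
        base = log_likelihood_score(dag, df, sch)
        names = [s.name for s in sch]
        # exhaustively re-evaluate every legal single-arc move
        for p, c in itertools.permutations(names, 2):
            cand = dag.copy()
            moves = []
            if not dag.has_arc(p, c):
                if dag.would_be_acyclic(p, c):
                    m = dag.copy(); m.add_arc(p, c); moves.append(m)
            else:
                m = dag.copy(); m.remove_arc(p, c); moves.append(m)
                m2 = dag.copy(); m2.remove_arc(p, c)
                if m2.would_be_acyclic(c, p):
                    m2.add_arc(c, p); moves.append(m2)
            for m in moves:
                assert log_likelihood_score(m, df, sch) - base <= cfg.epsilon + 1e-12

    def test_max_parents_respected(self):
        rng = np.random.default_rng(4)
        sch = [FeatureSchema(n, "categorical", ("0", "1")) for n in "ABCD"]
        df = pd.DataFrame({n: rng.choice(["0", "1"], size=40) for n in "ABCD"})
        dag = hill_climb(df, sch, LearnConfig(max_parents=1))
        assert all(len(dag.parents(n)) <= 1 for n in "ABCD")

    def test_clg_rule_no_continuous_parent_of_categorical(self):
        rng = np.random.default_rng(9)
        cat = rng.choice(["0", "1"], size=80)
        cont = np.where(cat == "1", 3.0, -3.0) + 0.3 * rng.normal(size=80)
        df = pd.DataFrame({"C": cat, "X": cont})
        sch = [FeatureSchema("C", "categorical", ("0", "1")),
               FeatureSchema("X", "continuous")]
        dag = hill_climb(df, sch)
        assert ("X", "C") not in dag.arcs
        assert ("C", "X") in dag.arcs  # strong dependence must be picked up


class TestLogicSample:
    def test_deterministic_bn_forces_configuration(self):
        sch = [FeatureSchema("A", "categorical", ("a", "b"))]
        cpd = DiscreteCpd("A", ("a", "b"), (), (), {(): np.array([0.0, 1.0])})
        bn = BayesianNetwork(Dag(["A"]), {"A": cpd}, sch)
        s = logic_sample(bn, 20, seed=0)
        assert (s["A"] == "b").all()

    def test_n_zero_gives_empty_table(self, discrete_problem):
        _, bn_pos, _, _ = discrete_problem
        s = logic_sample(bn_pos, 0, seed=0)
        assert len(s) == 0 and list(s.columns) == [x.name for x in bn_pos.schemas]

    def test_seed_reproducibility(self, discrete_problem):
        _, bn_pos, _, _ = discrete_problem
        a = logic_sample(bn_pos, 200, seed=42)
        b = logic_sample(bn_pos, 200, seed=42)
        assert a.equals(b)

    def test_chi2_goodness_of_fit_single_binary_node(self):
        from scipy import stats

        sch = [FeatureSchema("A", "categorical", ("0", "1"))]
        cpd = DiscreteCpd("A", ("0", "1"), (), (), {(): np.array([0.7, 0.3])})
        bn = BayesianNetwork(Dag(["A"]), {"A": cpd}, sch)
        s = logic_sample(bn, 10000, seed=5)
        obs = [(s["A"] == "0").sum(), (s["A"] == "1").sum()]
        _, p = stats.chisquare(obs, [7000, 3000])
        assert p > 0.001

    def test_continuous_sampling_matches_regression(self):
        sch = [FeatureSchema("X", "continuous"), FeatureSchema("Y", "continuous")]
        from bosme.bayesnet import LinearGaussianCpd
        cpds = {
            "X": LinearGaussianCpd("X", (), (), (), {(): (0.0, np.array([]), 1.0)}),
            "Y": LinearGaussianCpd("Y", (), (), ("X",), {(): (1.0, np.array([2.0]), 0.5)}),
        }
        bn = BayesianNetwork(Dag(["X", "Y"], [("X", "Y")]), cpds, sch)
        s = logic_sample(bn, 20000, seed=3)
        resid = s["Y"] - (1.0 + 2.0 * s["X"])
        assert resid.mean() == pytest.approx(0.0, abs=0.02)
        assert resid.std() == pytest.approx(0.5, abs=0.02)


class TestJoint:
    def test_chain_rule_product(self):
        sch = AB
        cpds = {
            "A": DiscreteCpd("A", ("0", "1"), (), (), {(): np.array([0.6, 0.4])}),
            "B": DiscreteCpd("B", ("0", "1"), ("A",), (("0", "1"),),
                             {("0",): np.array([0.9, 0.1]),
                              ("1",): np.array([0.5, 0.5])}),
        }
        bn = BayesianNetwork(Dag(["A", "B"], [("A", "B")]), cpds, sch)
        assert joint_probability(bn, {"A": "1", "B": "1"}) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(3))
    def test_joint_sums_to_one(self, seed):
        from bosme.synthdata import GroundTruthSpec, random_ground_truth_bn

        spec = GroundTruthSpec(n_features=3, kinds=[2, 2, 3], arc_density=1.0, seed=seed)
        bn = random_ground_truth_bn(spec, "positive")
        assert sum(enumerate_joint(bn).values()) == pytest.approx(1.0, abs=1e-9)

    def test_value_outside_levels_errors(self):
        sch = [FeatureSchema("A", "categorical", ("a", "b"))]
        cpd = DiscreteCpd("A", ("a", "b"), (), (), {(): np.array([0.5, 0.5])})
        bn = BayesianNetwork(Dag(["A"]), {"A": cpd}, sch)
        with pytest.raises(Exception, match="outside levels"):
            joint_probability(bn, {"A": "z"})


class TestSamplerEstimator:
    def test_fit_sample_score_roundtrip(self, discrete_problem):
        _, bn_pos, _, table = discrete_problem
        names = [s.name for s in bn_pos.schemas]
        minority = table.df[table.df["V"] == "+"][names]
        est = BayesianNetworkSampler(max_parents=2)
        est.fit(minority, schemas=list(bn_pos.schemas))
        assert hasattr(est, "network_") and hasattr(est, "dag_")
        s = est.sample(10, seed=0)
        assert len(s) == 10 and list(s.columns) == names
        assert np.isfinite(est.score(minority))

    def test_get_set_params(self):
        est = BayesianNetworkSampler().set_params(epsilon=0.5)
        assert est.get_params()["epsilon"] == 0.5

    def test_json_roundtrip(self, discrete_problem):
        _, bn_pos, _, _ = discrete_problem
        doc = bn_pos.to_dict()
        bn2 = BayesianNetwork.from_dict(doc)
        inst = {s.name: s.levels[0] for s in bn_pos.schemas}
        assert joint_probability(bn2, inst) == pytest.approx(
            joint_probability(bn_pos, inst))


def test_total_variation_sampling_consistency():
    """Empirical distribution of forward samples approaches the chain-rule
    joint: TV < 0.02 at n = 50,000 on a 3-node binary network."""
    from bosme.synthdata import GroundTruthSpec, random_ground_truth_bn

    spec = GroundTruthSpec(n_features=3, kinds=[2, 2, 2], arc_density=1.0, seed=1)
    bn = random_ground_truth_bn(spec, "positive")
    true_j = enumerate_joint(bn)
    n = 50_000
    s = logic_sample(bn, n, seed=9)
    emp = s.groupby(list(s.columns)).size() / n
    tv = 0.5 * sum(abs(true_j[cfg] - emp.get(cfg, 0.0)) for cfg in true_j)
    assert tv < 0.02
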