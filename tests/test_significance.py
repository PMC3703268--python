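import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathprop.errors import ConfigurationError
from pathprop.graph import normalized_adjacency
from pathprop.propagation import PropagationConfig
from pathprop.scoring import (
    PathwayActivityMatrix,
    PathwayCollection,
    make_pathway,
)
from pathprop.seeds import ActivityVector
from pathprop.significance import (
    PermutationConfig,
    SelectionCriteria,
    bh_adjust,
    empirical_pvalues,
    permutation_null,
    select_common,
    select_per_cancer,
    select_specific,
)

from conftest import random_network


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min_{j: p_j >= p_i over rank} ..."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(pos, n)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestPermutationNull:
    def setup_instance(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n, p=0.1)
        gbar = normalized_adjacency(net)
        g = ActivityVector(rng.random(n))
        coll = PathwayCollection([
            make_pathway(f"P{j}", "d", list(rng.choice(net.nodes, 6, replace=False)))
            for j in range(5)
        ])
        return net, gbar, g, coll

    def test_deterministic_given_seed(self):
        net, gbar, g, coll = self.setup_instance()
        cfg = PermutationConfig(n_permutations=20, mode="both", rng_seed=42)
        prop = PropagationConfig()
        a, _ = permutation_null(net, gbar, g, coll, cfg, prop)
        b, _ = permutation_null(net, gbar, g, coll, cfg, prop)
        assert np.array_equal(a, b)

    def test_whole_network_pathway_constant_null(self):
        net, gbar, g, _ = self.setup_instance()
        coll = PathwayCollection([make_pathway("ALL", "d", list(net.nodes))])
        cfg = PermutationConfig(n_permutations=10, mode="membership", rng_seed=1)
        nulls, _ = permutation_null(net, gbar, g, coll, cfg, PropagationConfig())
        assert np.allclose(nulls, nulls[0, 0])

    def test_zero_permutations_rejected(self):
        with pytest.raises(ConfigurationError):
            PermutationConfig(n_permutations=0)

    def test_membership_mode_calibration(self):
        # i.i.d. scores, random size-matched pathways: p approximately uniform
        rng = np.random.default_rng(7)
        net = random_network(rng, 400, p=0.02)
        gbar = normalized_adjacency(net)
        g = ActivityVector(rng.random(net.n_nodes))
        coll = PathwayCollection([
            make_pathway(f"P{j:03d}", "d", list(rng.choice(net.nodes, 8, replace=False)))
            for j in range(200)
        ])
        cfg = PermutationConfig(n_permutations=999, mode="membership", rng_seed=11)
        prop = PropagationConfig()
        nulls, names = permutation_null(net, gbar, g, coll, cfg, prop)
        from pathprop.propagation import propagate_closed_form
        gt = propagate_closed_form(gbar, g, prop)
        from pathprop.scoring import pathway_activity
        observed = pathway_activity(gt, coll, net, min_members=1)["score"]
        p = empirical_pvalues(observed, nulls, names=names)
        from scipy.stats import kstest
        assert kstest(p.to_numpy(), "uniform").pvalue > 0.01


class TestEmpiricalPvalues:
    def test_exceeds_all(self):
        obs = pd.Series({"P": 10.0})
        nulls = np.zeros((999, 1))
        p = empirical_pvalues(obs, nulls)
        assert p["P"] == pytest.approx(1 / 1000)

    def test_below_all(self):
        obs = pd.Series({"P": -1.0})
        nulls = np.zeros((99, 1))
        assert empirical_pvalues(obs, nulls)["P"] == pytest.approx(1.0)

    def test_direct_count_oracle(self):
        obs = pd.Series({"P": 0.5})
        nulls = np.array([[0.6], [0.7], [0.1], [0.2], [0.3], [0.1], [0.0], [0.2], [0.4]])
        # B=9, exactly 2 nulls >= 0.5 -> (1+2)/10
        assert empirical_pvalues(obs, nulls)["P"] == pytest.approx(0.3)

    def test_missing_null_errors(self):
        obs = pd.Series({"P": 0.5})
        nulls = np.full((5, 1), np.nan)
        with pytest.raises(ValueError, match="missing null"):
            empirical_pvalues(obs, nulls)

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(0)
        nulls = rng.random((200, 1))
        values = np.linspace(0, 1, 11)
        ps = [
            empirical_pvalues(pd.Series({"P": v}), nulls)["P"] for v in values
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_range(self):
        rng = np.random.default_rng(1)
        nulls = rng.random((50, 1))
        for v in rng.random(20):
            p = empirical_pvalues(pd.Series({"P": v}), nulls)["P"]
            assert 0 < p <= 1


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_constant_vector(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        # family size 2: q = [min(0.02, 0.04), 0.04]
        assert q[0] == pytest.approx(0.02)
        assert q[2] == pytest.approx(0.04)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            p = rng.random(int(rng.integers(1, 25)))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_oracle_property(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def build_matrix(scores, qvalues, collections=None):
    s = pd.DataFrame(scores).T if isinstance(scores, dict) else scores
    q = pd.DataFrame(qvalues).T if isinstance(qvalues, dict) else qvalues
    return PathwayActivityMatrix(
        scores=s,
        coverage=s.notna().astype(int),
        collections=collections,
        p_values=q,
        q_values=q,
    )


class TestSelectPerCancer:
    def test_top_fraction_cap(self):
        names = [f"P{i}" for i in range(10)]
        scores = pd.DataFrame([np.arange(10, 0, -1.0)], index=["c"], columns=names)
        q = pd.DataFrame([np.full(10, 1e-4)], index=["c"], columns=names)
        matrix = build_matrix(scores, q)
        sel = select_per_cancer(
            matrix, SelectionCriteria(per_cancer_top_fraction=0.20),
            {"default": 0.05},
        )
        assert len(sel["c"]) == 2
        assert sel["c"] == ["P0", "P1"]

    def test_q_cutoff_excludes(self):
        scores = pd.DataFrame([[5.0, 4.0]], index=["c"], columns=["A", "B"])
        q = pd.DataFrame([[0.5, 1e-4]], index=["c"], columns=["A", "B"])
        matrix = build_matrix(scores, q)
        sel = select_per_cancer(
            matrix, SelectionCriteria(per_cancer_top_fraction=1.0),
            {"default": 0.005},
        )
        assert sel["c"] == ["B"]

    def test_hand_evaluation(self):
        names = ["P1", "P2", "P3", "P4", "P5"]
        scores = pd.DataFrame([[9.0, 8.0, 7.0, 2.0, 1.0]], index=["c"], columns=names)
        q = pd.DataFrame([[1e-4, 0.9, 1e-4, 1e-4, 1e-4]], index=["c"], columns=names)
        matrix = build_matrix(scores, q)
        # top 40% of 5 -> ceil(2.0)=2 -> {P1,P2}; P2 fails q -> {P1}
        sel = select_per_cancer(
            matrix, SelectionCriteria(per_cancer_top_fraction=0.40),
            {"default": 0.05},
        )
        assert sel["c"] == ["P1"]

    def test_missing_q_errors(self):
        scores = pd.DataFrame([[1.0]], index=["c"], columns=["P"])
        matrix = PathwayActivityMatrix(
            scores=scores, coverage=scores.notna().astype(int)
        )
        with pytest.raises(ValueError, match="q-values"):
            select_per_cancer(matrix, SelectionCriteria(), {"default": 0.05})


def recurrence_matrix(n_cancers, qualifying_cancers, n_pathways=10, target="P0"):
    """One planted pathway with top score and tiny q in a subset of cancers."""
    names = [f"P{i}" for i in range(n_pathways)]
    cancers = [f"c{i}" for i in range(n_cancers)]
    rng = np.random.default_rng(0)
    scores = pd.DataFrame(
        rng.uniform(0, 1, size=(n_cancers, n_pathways)), index=cancers, columns=names
    )
    q = pd.DataFrame(0.9, index=cancers, columns=names)
    for c in qualifying_cancers:
        scores.loc[c, target] = 10.0
        q.loc[c, target] = 1e-4
    return build_matrix(scores, q)


class TestSelectCommon:
    def test_threshold_rule(self):
        m = recurrence_matrix(16, [f"c{i}" for i in range(11)])
        common = select_common(
            m, SelectionCriteria(min_cancer_types=10), {"default": 0.05}
        )
        assert list(common["pathway"]) == ["P0"]
        assert common["n_cancers"].iloc[0] == 11

    def test_below_threshold_excluded(self):
        m = recurrence_matrix(16, [f"c{i}" for i in range(9)])
        common = select_common(
            m, SelectionCriteria(min_cancer_types=10), {"default": 0.05}
        )
        assert common.empty

    def test_planted_fixture_exact_recovery(self):
        m = recurrence_matrix(16, [f"c{i}" for i in range(12)], n_pathways=30)
        common = select_common(
            m, SelectionCriteria(min_cancer_types=10, common_top_fraction=0.10),
            {"default": 0.05},
        )
        assert list(common["pathway"]) == ["P0"]

    def test_monotone_in_min_cancers(self):
        m = recurrence_matrix(16, [f"c{i}" for i in range(12)])
        loose = select_common(
            m, SelectionCriteria(min_cancer_types=1), {"default": 0.05}
        )
        strict = select_common(
            m, SelectionCriteria(min_cancer_types=10), {"default": 0.05}
        )
        assert set(strict["pathway"]) <= set(loose["pathway"])


class TestSelectSpecific:
    def test_reported_under_each_qualifying_cancer(self):
        m = recurrence_matrix(16, ["c0", "c1"])
        specific = select_specific(
            m, SelectionCriteria(), {"default": 0.05}, max_cancer_types=2
        )
        assert specific == {"c0": ["P0"], "c1": ["P0"]}

    def test_widely_disrupted_excluded(self):
        m = recurrence_matrix(16, [f"c{i}" for i in range(10)])
        specific = select_specific(
            m, SelectionCriteria(), {"default": 0.05}, max_cancer_types=2
        )
        assert specific == {}


def test_global_null_false_positive_rate():
    """i.i.d. scores + random pathways: ~5% of p-values below 0.05."""
    rng = np.random.default_rng(123)
    net = random_network(rng, 500, p=0.016)
    gbar = normalized_adjacency(net)
    g = ActivityVector(rng.random(net.n_nodes))
    coll = PathwayCollection([
        make_pathway(f"P{j:03d}", "d", list(rng.choice(net.nodes, 10, replace=False)))
        for j in range(500)
    ])
    cfg = PermutationConfig(n_permutations=999, mode="membership", rng_seed=5)
    prop = PropagationConfig()
    nulls, names = permutation_null(net, gbar, g, coll, cfg, prop)
    from pathprop.propagation import propagate_closed_form
    from pathprop.scoring import pathway_activity
    gt = propagate_closed_form(gbar, g, prop)
    observed = pathway_activity(gt, coll, net, min_members=1)["score"]
    p = empirical_pvalues(observed, nulls, names=names)
    frac = float((p < 0.05).mean())
    assert 0.03 <= frac <= 0.07
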