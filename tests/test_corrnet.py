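"""Spearman/BH kernels against independent oracles and network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from exponet import OmicsBlock, bh_adjust, build_network, degree_table, spearman_rho
from exponet.corrnet import CorrelationNetwork


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} p_(j)*N/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * n / j for j in range(rank_pos, n + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def spearman_footrule_oracle(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
            ([1, 2, 3, 4, 5], [3, 1, 2, 5, 4], 0.6),
        ],
    )
    def test_known_values(self, x, y, expected):
        rho, p, n = spearman_rho(x, y, min_n=4)
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == len(x)

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rho, _, _ = spearman_rho(x, y)
            assert rho == pytest.approx(spearman_footrule_oracle(x, y), abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 4, size=15).astype(float)
        y = rng.integers(0, 4, size=15).astype(float)
        rho, p, _ = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=18)
        y = rng.normal(size=18)
        r0, _, _ = spearman_rho(x, y)
        r1, _, _ = spearman_rho(np.exp(x), y)
        r2, _, _ = spearman_rho(x, y**3)
        assert r0 == pytest.approx(r1, abs=1e-12) == pytest.approx(r2, abs=1e-12)

    def test_pairwise_deletion_and_min_n(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([2, 4, 6, 8, 10, np.nan])
        rho, _, n = spearman_rho(x, y, min_n=4)
        assert rho == 1.0 and n == 4
        with pytest.raises(ValueError, match="complete pairs"):
            spearman_rho(x, y, min_n=5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], min_n=5)


class TestBH:
    def test_single_and_hand_worked(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            p = rng.random(size=rng.integers(1, 30))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_monotone_after_sorting_and_bounded(self, ps):
        q = bh_adjust(ps)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _block(values, ome):
    values = np.asarray(values, dtype=float)
    return OmicsBlock(
        ome_label=ome,
        data=pd.DataFrame(values, index=[f"{ome}{i}" for i in range(values.shape[0])],
                          columns=[f"S{j}" for j in range(values.shape[1])]),
    )


class TestBuildNetwork:
    def test_perfect_monotone_pair_recovered(self, rng):
        x = np.sort(rng.normal(size=18))
        blocks = {
            "a": _block([x, rng.normal(size=18)], "a"),
            "b": _block([2 * x + 1, rng.normal(size=18)], "b"),
        }
        net = build_network(blocks, [("a", "b")])
        keys = {frozenset((e.source, e.target)) for e in net.edges}
        assert frozenset(((("a", "a0")), ("b", "b0"))) in keys
        edge = [e for e in net.edges if frozenset((e.source, e.target)) == frozenset((("a", "a0"), ("b", "b0")))][0]
        assert edge.rho == pytest.approx(1.0)

    def test_intra_block_has_no_self_edges(self, rng):
        blocks = {"a": _block(rng.normal(size=(6, 18)), "a")}
        net = build_network(blocks, [("a", "a")], r_min=-0.01, q_max=1.1)
        for e in net.edges:
            assert e.source != e.target
        # unordered pairs only: C(6,2) = 15 edges at permissive thresholds
        assert net.n_edges == 15

    def test_edge_set_matches_bruteforce_recomputation(self, rng):
        a = rng.normal(size=(20, 18))
        b = rng.normal(size=(20, 18))
        blocks = {"a": _block(a, "a"), "b": _block(b, "b")}
        net = build_network(blocks, [("a", "b")], r_min=0.3, q_max=0.2)
        # independent oracle: scipy spearman per pair + oracle BH
        ps, rhos = [], []
        for i in range(20):
            for j in range(20):
                r = stats.spearmanr(a[i], b[j])
                rhos.append(r.statistic)
                ps.append(r.pvalue)
        qs = bh_oracle(np.array(ps))
        expected = {
            (f"a{i}", f"b{j}")
            for k, (i, j) in enumerate([(i, j) for i in range(20) for j in range(20)])
            if abs(rhos[k]) > 0.3 and qs[k] < 0.2
        }
        got = {(e.source[1], e.target[1]) for e in net.edges}
        assert got == expected

    def test_invariant_to_feature_and_block_order(self, rng):
        a = rng.normal(size=(8, 18))
        b = rng.normal(size=(8, 18))
        blocks = {"a": _block(a, "a"), "b": _block(b, "b")}
        net1 = build_network(blocks, [("a", "b")], r_min=0.3, q_max=0.3)
        perm = rng.permutation(8)
        a_perm = _block(a[perm], "a")
        a_perm.data.index = [f"a{i}" for i in perm]
        blocks2 = {"b": _block(b, "b"), "a": a_perm}
        net2 = build_network(blocks2, [("a", "b")], r_min=0.3, q_max=0.3)
        key = lambda n: {frozenset((e.source, e.target)) for e in n.edges}
        assert key(net1) == key(net2)


class TestDegreeTable:
    def test_star_and_tie_breaks(self, rng):
        x = np.sort(rng.normal(size=18))
        center = [x]
        leaves = [x + rng.normal(scale=1e-9, size=18) for _ in range(5)]
        blocks = {"hub": _block(center, "hub"), "leaf": _block(leaves, "leaf")}
        net = build_network(blocks, [("hub", "leaf")])
        table = degree_table(net, min_degree=3)
        assert list(table["feature"]) == ["hub0"]
        assert int(table["degree"].iloc[0]) == 5
        full = degree_table(net, min_degree=0)
        ties = full[full["degree"] == 1]
        assert list(ties["feature"]) == sorted(ties["feature"])
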