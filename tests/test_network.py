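import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmra.network import (
    MiNetwork,
    apply_dpi,
    build_mi_network,
    build_mi_null,
    default_n_bins,
    mutual_information,
)
from tmra.simulate import generate_dataset

from conftest import make_dataset, small_config


# --- independent oracles -------------------------------------------------

def oracle_rank_bins(v, n_bins):
    """Average ranks, empirical-quantile edges, right-closed cells —
    recomputed with plain Python."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    sr = sorted(ranks)
    n = len(sr)

    def quantile(q):  # linear interpolation, as np.quantile default
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return sr[lo] + (h - lo) * (sr[hi] - sr[lo])

    edges = [quantile(k / n_bins) for k in range(1, n_bins)]
    bins = []
    for r in ranks:
        b = 0
        while b < len(edges) and r > edges[b]:
            b += 1
        bins.append(b)
    return bins


def oracle_mi(x, y, n_bins):
    """Joint-histogram plug-in MI recomputed from scratch."""
    bx = oracle_rank_bins(list(x), n_bins)
    by = oracle_rank_bins(list(y), n_bins)
    n = len(bx)
    joint = {}
    mx, my = {}, {}
    for a, b in zip(bx, by):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        mx[a] = mx.get(a, 0) + 1
        my[b] = my.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log(p / ((mx[a] / n) * (my[b] / n)))
    return mi


def oracle_dpi(edges, tolerance):
    """Exhaustive triple enumeration; simultaneous removal."""
    mi = {frozenset(e): m for e, m in edges.items()}
    nodes = sorted({n for e in mi for n in e})
    doomed = set()
    for i in nodes:
        for j in nodes:
            if j <= i:
                continue
            if frozenset((i, j)) not in mi:
                continue
            for k in nodes:
                if k in (i, j):
                    continue
                e1, e2 = frozenset((i, k)), frozenset((j, k))
                if e1 in mi and e2 in mi:
                    mij = mi[frozenset((i, j))]
                    if mij < (1 - tolerance) * mi[e1] and mij < (
                        1 - tolerance
                    ) * mi[e2]:
                        doomed.add(frozenset((i, j)))
    return {e for e in mi if e not in doomed}


def network_from_dict(edges, tfs):
    rows = [(tuple(sorted(e))[0], tuple(sorted(e))[1], m, 0.001)
            for e, m in edges.items()]
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "p_value"])
    return MiNetwork(frame, tfs)


# --- mutual information --------------------------------------------------

class TestMutualInformation:
    def test_identity_map_reaches_log_bins(self):
        x = np.arange(64.0)
        assert mutual_information(x, x, 8) == pytest.approx(np.log(8), abs=1e-12)

    def test_factorial_grid_is_exactly_independent(self):
        x = np.arange(64.0)
        y = np.array([(i % 8) * 8 + i // 8 for i in range(64)], dtype=float)
        assert mutual_information(x, y, 8) == 0.0

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            bins = int(rng.integers(2, max(3, n // 10 + 1)))
            rho = rng.uniform(-0.95, 0.95)
            cov = [[1, rho], [rho, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            x, y = xy[:, 0], xy[:, 1]
            if rng.random() < 0.3:  # exercise tie handling
                x = np.round(x, 1)
            assert mutual_information(x, y, bins) == pytest.approx(
                oracle_mi(x, y, bins), abs=1e-12
            )

    def test_bivariate_normal_against_oracle(self):
        rng = np.random.default_rng(7)
        xy = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=500)
        got = mutual_information(xy[:, 0], xy[:, 1], 8)
        assert got == pytest.approx(oracle_mi(xy[:, 0], xy[:, 1], 8), abs=1e-12)
        assert got > 0.3  # strong dependence is visible

    @pytest.mark.parametrize(
        "x,y,err",
        [
            (np.arange(10.0), np.arange(9.0), "length"),
            (np.ones(20), np.arange(20.0), "constant"),
        ],
    )
    def test_degenerate_inputs_rejected(self, x, y, err):
        with pytest.raises(ValueError, match=err):
            mutual_information(x, y, 2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 60))
        x = rng.standard_normal(n)
        y = x * rng.uniform(-1, 1) + rng.standard_normal(n)
        mi = mutual_information(x, y, 4)
        assert mi >= 0
        assert mutual_information(y, x, 4) == pytest.approx(mi, abs=1e-12)
        # strictly monotone marginal transforms leave ranks unchanged
        assert mutual_information(np.exp(x), y**3 + 2 * y, 4) == pytest.approx(
            mi, abs=1e-12
        )


# --- pooled null ---------------------------------------------------------

class TestMiNull:
    def test_deterministic_nonnegative_and_ordered(self, small_planted):
        dataset, _ = small_planted
        n1 = build_mi_null(dataset, n_perm_pairs=1000, seed=5)
        n2 = build_mi_null(dataset, n_perm_pairs=1000, seed=5)
        assert np.array_equal(n1.null_mis, n2.null_mis)
        assert (n1.null_mis >= 0).all()
        q995, q50 = np.quantile(n1.null_mis, [0.995, 0.5])
        assert q995 > q50

    def test_too_few_pairs_rejected(self, small_planted):
        with pytest.raises(ValueError, match="1000"):
            build_mi_null(small_planted[0], n_perm_pairs=10, seed=0)


# --- network construction ------------------------------------------------

class TestBuildNetwork:
    def test_planted_edges_retained_at_high_coupling(self):
        # beta/sigma = 2: nearly every true TF->target edge survives
        rates = []
        for seed in (1, 2, 3):
            cfg = small_config(seed=seed, coupling=2.0)
            ds, truth = generate_dataset(cfg)
            null = build_mi_null(ds, n_perm_pairs=2000, seed=seed + 100)
            net = build_mi_network(ds, truth.tf_genes, null)
            kept = {
                frozenset((r.gene_a, r.gene_b))
                for r in net.edges.itertuples(index=False)
            }
            true_edges = [
                frozenset((tf, t))
                for tf in truth.regulons
                for t in truth.regulons.targets(tf)
            ]
            rates.append(sum(e in kept for e in true_edges) / len(true_edges))
        assert min(rates) >= 0.99

    def test_noise_data_retention_is_calibrated(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(
            rng.standard_normal((120, 160)),
            [f"G{i}" for i in range(120)],
            [f"s{i}" for i in range(160)], 100,
        )
        null = build_mi_null(ds, n_perm_pairs=5000, seed=9)
        net = build_mi_network(ds, [f"G{i}" for i in range(10)], null, alpha=0.005)
        n_tested = 10 * 119 - math.comb(10, 2)
        assert net.n_edges() / n_tested <= 2 * 0.005

    def test_disjoint_tf_list_is_an_error(self, small_planted):
        dataset, _ = small_planted
        null = build_mi_null(dataset, n_perm_pairs=1000, seed=1)
        with pytest.raises(ValueError, match="no TF"):
            build_mi_network(dataset, ["NOPE1", "NOPE2"], null)


# --- DPI -----------------------------------------------------------------

class TestApplyDpi:
    def triangle(self, m_ab, m_ac, m_bc):
        return network_from_dict(
            {("A", "B"): m_ab, ("A", "C"): m_ac, ("B", "C"): m_bc},
            ["A", "B", "C"],
        )

    def test_weakest_edge_removed_when_clearly_dominated(self):
        net = apply_dpi(self.triangle(0.1, 0.5, 0.4), 0.2)
        kept = {
            frozenset((r.gene_a, r.gene_b))
            for r in net.edges.itertuples(index=False)
        }
        assert kept == {frozenset(("A", "C")), frozenset(("B", "C"))}

    def test_close_triangle_left_intact(self):
        net = apply_dpi(self.triangle(0.4, 0.5, 0.45), 0.2)
        assert net.n_edges() == 3

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(77)
        for rep in range(500):
            n_nodes = int(rng.integers(3, 7))
            nodes = [f"N{i}" for i in range(n_nodes)]
            edges = {}
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    if rng.random() < 0.6:
                        edges[(nodes[i], nodes[j])] = float(
                            rng.uniform(0.01, 1.0)
                        )
            if not edges:
                continue
            tol = float(rng.choice([0.0, 0.1, 0.2, 0.5]))
            net = apply_dpi(network_from_dict(edges, nodes), tol)
            kept = {
                frozenset((r.gene_a, r.gene_b))
                for r in net.edges.itertuples(index=False)
            }
            expected = oracle_dpi(
                {frozenset(e): m for e, m in edges.items()}, tol
            )
            assert kept == expected, f"rep={rep} tol={tol}"

    def test_tolerance_extremes(self):
        # tolerance 0 removes every strict-minimum triangle edge;
        # tolerance near 1 removes nothing
        net = self.triangle(0.3, 0.5, 0.4)
        assert apply_dpi(net, 0.0).n_edges() == 2
        assert apply_dpi(net, 0.99).n_edges() == 3

    def test_output_subset_with_unchanged_mi(self):
        net = self.triangle(0.1, 0.5, 0.4)
        out = apply_dpi(net, 0.2)
        merged = out.edges.merge(
            net.edges, on=["gene_a", "gene_b"], suffixes=("", "_in")
        )
        assert (merged["mi"] == merged["mi_in"]).all()


def test_default_bin_rule():
    assert default_n_bins(150) == 5
    assert default_n_bins(6) == 2
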