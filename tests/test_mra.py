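import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tmra.mra import (
    coverage_curve,
    gsea_es,
    nes_and_p,
    p_from_nes,
    regulon_es,
    run_mra,
)
from tmra.regulons import Interaction, RegulonSet
from tmra.signature import MolecularSignature
from tmra.simulate import generate_dataset

from conftest import small_config


def sig_from(z_by_gene: dict) -> MolecularSignature:
    return MolecularSignature(pd.Series(z_by_gene, name="z"), 10, 10)


def oracle_gsea(z: pd.Series, members, weights=None):
    """Position-by-position running-sum recomputation."""
    ranked = sorted(z.index, key=lambda g: (-z[g], g))
    m_set = set(members) & set(z.index)
    n, m = len(ranked), len(m_set)
    total = sum(
        abs(z[g]) * (weights.get(g, 1.0) if weights else 1.0)
        for g in ranked if g in m_set
    )
    running, best = 0.0, 0.0
    for g in ranked:
        if g in m_set:
            if total > 0:
                w = abs(z[g]) * (weights.get(g, 1.0) if weights else 1.0)
                running += w / total
            else:
                running += 1 / m
        else:
            running -= 1 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaEs:
    def test_single_top_member_peaks_at_one(self):
        sig = sig_from({"A": 3.0, "B": 2.0, "C": -2.0, "D": -3.0})
        assert gsea_es(sig, ["A"]) == pytest.approx(1.0)

    def test_single_bottom_member_is_minus_one(self):
        sig = sig_from({"A": 3.0, "B": 2.0, "C": -2.0, "D": -3.0})
        assert gsea_es(sig, ["D"]) == pytest.approx(-1.0)

    def test_matches_running_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            n = int(rng.integers(5, 31))
            genes = [f"G{i:02d}" for i in range(n)]
            z = pd.Series(np.round(rng.standard_normal(n), 3), index=genes)
            m = int(rng.integers(1, n))
            members = list(rng.choice(genes, m, replace=False))
            weights = None
            if rng.random() < 0.5:
                weights = {g: float(rng.uniform(0.1, 1)) for g in members}
            got = gsea_es(z, members, weights)
            assert got == pytest.approx(
                oracle_gsea(z, members, weights), abs=1e-12
            )

    def test_degenerate_member_sets_rejected(self):
        sig = sig_from({"A": 1.0, "B": 0.5})
        with pytest.raises(ValueError, match="empty"):
            gsea_es(sig, ["ZZ"])
        with pytest.raises(ValueError, match="universe"):
            gsea_es(sig, ["A", "B"])


class TestRegulonEs:
    def test_all_positive_modes_reduce_to_plain_es(self):
        sig = sig_from({f"G{i}": float(5 - i) for i in range(6)})
        targets = ["G0", "G1"]
        modes = np.array([0.5, 0.0])  # zero mode counts as positive
        ws = np.array([1.0, 1.0])
        assert regulon_es(targets, modes, ws, sig) == pytest.approx(
            gsea_es(sig.z, targets)
        )

    def test_flipping_modes_and_z_leaves_es_unchanged(self):
        rng = np.random.default_rng(55)
        genes = [f"G{i:02d}" for i in range(20)]
        z = pd.Series(rng.standard_normal(20), index=genes)
        targets = genes[:8]
        modes = rng.choice([-0.7, 0.7], 8)
        ws = rng.uniform(0.2, 1.0, 8)
        sig = MolecularSignature(z, 5, 5)
        flipped = MolecularSignature(-z, 5, 5)
        es1 = regulon_es(targets, modes, ws, sig)
        es2 = regulon_es(targets, -modes, ws, flipped)
        assert es2 == pytest.approx(es1, abs=1e-12)

    def test_planted_differential_regulators_score_negative(self, small_planted):
        ds, truth = small_planted
        from tmra.signature import compute_signature

        sig = compute_signature(ds, truth.pathways)
        for tf in truth.diff_tfs:
            inters = truth.regulons[tf]
            es = regulon_es(
                [i.target for i in inters],
                np.array([i.mode for i in inters]),
                np.array([i.weight for i in inters]),
                sig,
            )
            assert es < 0

    def test_target_order_is_irrelevant(self):
        rng = np.random.default_rng(66)
        genes = [f"G{i:02d}" for i in range(15)]
        sig = sig_from(dict(zip(genes, rng.standard_normal(15))))
        targets = genes[:6]
        modes = rng.choice([-1.0, 1.0], 6)
        ws = rng.uniform(0.1, 1.0, 6)
        es = regulon_es(targets, modes, ws, sig)
        perm = rng.permutation(6)
        es2 = regulon_es(
            [targets[i] for i in perm], modes[perm], ws[perm], sig
        )
        assert es2 == pytest.approx(es, abs=1e-12)


class TestNesAndP:
    def test_standardization_and_gaussian_tail(self):
        rng = np.random.default_rng(12)
        null = rng.standard_normal(100_000)
        nes, p = nes_and_p(1.96, null)
        assert p == pytest.approx(0.05, abs=0.005)
        nes0, p0 = nes_and_p(float(null.mean()), null)
        assert nes0 == pytest.approx(0.0, abs=1e-12)
        assert p0 == pytest.approx(1.0)

    def test_zero_variance_null_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            nes_and_p(0.5, np.full(200, 0.3))

    def test_p_strictly_decreasing_in_abs_nes(self):
        ps = [p_from_nes(x) for x in np.linspace(0, 6, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


@pytest.fixture(scope="module")
def planted_result(small_signature_null, small_planted):
    sig, null = small_signature_null
    _, truth = small_planted
    return run_mra(truth.regulons, sig, null, min_targets=5)


class TestRunMra:
    def test_planted_tfs_rank_first(self, planted_result, small_planted):
        _, truth = small_planted
        top = list(planted_result.sort_values("rank").head(5)["regulon"])
        assert set(top) == set(truth.diff_tfs)

    def test_fast_path_matches_reference_es(
        self, planted_result, small_planted, small_signature_null
    ):
        sig, _ = small_signature_null
        _, truth = small_planted
        for row in planted_result.head(8).itertuples(index=False):
            inters = truth.regulons[row.regulon]
            ref = regulon_es(
                [i.target for i in inters],
                np.array([i.mode for i in inters]),
                np.array([i.weight for i in inters]),
                sig,
            )
            assert row.es == pytest.approx(ref, abs=1e-9)

    def test_size_filter_semantics(self, small_signature_null):
        sig, null = small_signature_null
        genes = sig.genes
        reg = RegulonSet(
            {
                "TFBIG": [Interaction(g, 1.0, 1.0) for g in genes[:20]],
                "TFSMALL": [Interaction(g, 1.0, 1.0) for g in genes[20:39]],
            }
        )
        res = run_mra(reg, sig, null, min_targets=20)
        assert list(res["regulon"]) == ["TFBIG"]
        with pytest.raises(ValueError, match="no regulon"):
            run_mra(reg, sig, null, min_targets=50)

    def test_result_schema_and_fdr_range(self, planted_result):
        assert list(planted_result["rank"]) == list(
            range(1, len(planted_result) + 1)
        )
        assert planted_result["p_value"].between(0, 1).all()
        assert planted_result["fdr"].between(0, 1).all()
        # ranking follows ascending p
        assert (planted_result["p_value"].diff().dropna() >= 0).all()


class TestCoverageCurve:
    def build(self, regulon_sizes, signature_size):
        genes = [f"G{i:04d}" for i in range(signature_size)]
        regulons, start = {}, 0
        for t, size in enumerate(regulon_sizes):
            regulons[f"TF{t:02d}"] = [
                Interaction(g, 1.0, 1.0) for g in genes[start:start + size]
            ]
            start += size
        table = pd.DataFrame(
            {
                "regulon": list(regulons),
                "rank": range(1, len(regulons) + 1),
            }
        )
        return table, RegulonSet(regulons), genes

    def test_disjoint_regulons_give_linear_fraction(self):
        table, reg, genes = self.build([10] * 10, 100)
        cov = coverage_curve(table, reg, genes)
        assert list(cov["fraction"]) == pytest.approx(
            [k / 10 for k in range(1, 11)]
        )

    def test_matches_set_union_oracle_with_overlap(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i:03d}" for i in range(120)]
        regulons = {
            f"TF{t}": [
                Interaction(g, 1.0, 1.0)
                for g in rng.choice(genes, rng.integers(5, 40), replace=False)
            ]
            for t in range(6)
        }
        reg = RegulonSet(regulons)
        table = pd.DataFrame(
            {"regulon": list(regulons), "rank": range(1, 7)}
        )
        sig = list(rng.choice(genes, 80, replace=False))
        cov = coverage_curve(table, reg, sig)
        union = set()
        for k, tf in enumerate(table["regulon"], 1):
            union |= set(reg.targets(tf)) & set(sig)
            assert cov.loc[k - 1, "covered"] == len(union)
        assert (cov["covered"].diff().dropna() >= 0).all()
        assert cov["fraction"].iloc[-1] <= 1
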