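import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epinet.de import DERecord
from epinet.expression import (build_epistasis_table, epsilon_exp,
                               flag_significant, geneset_summary, moments,
                               read_gene_set, sign_balance,
                               standardize_epsilon)


def recs(cid, **genes):
    """genes maps gene -> (log2fc, q)."""
    return [DERecord(g, cid, lfc, q / 2, q) for g, (lfc, q) in genes.items()]


class TestEpsilonExp:
    @pytest.mark.parametrize("gx,gy,gxy,expected", [
        (1.0, 2.0, 3.0, 0.0),
        (1.0, 2.0, 4.0, 1.0),
        (-0.5, 0.5, -1.0, -1.0),
    ])
    def test_additive_null(self, gx, gy, gxy, expected):
        assert epsilon_exp(gx, gy, gxy) == pytest.approx(expected)

    @given(gx=st.floats(-5, 5), gy=st.floats(-5, 5), d=st.floats(-5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_deviation_from_additivity_is_recovered_exactly(self, gx, gy, d):
        assert epsilon_exp(gx, gy, gx + gy + d) == pytest.approx(d, abs=1e-9)


class TestStandardize:
    def test_hand_example(self):
        z = standardize_epsilon([-1.0, 0.0, 1.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize_epsilon([0.5, 0.5, 0.5])

    def test_output_is_standardized(self, rng):
        z = standardize_epsilon(rng.normal(2, 3, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestFlagging:
    @staticmethod
    def _table(z):
        return pd.DataFrame({"gene": ["a"], "double_id": ["d"], "ge_x": [0.0],
                             "ge_y": [0.0], "ge_xy": [0.0], "epsilon_exp": [0.0],
                             "z": [z]})

    def test_tier_a_needs_one_significant_contrast(self):
        tables = {"x": recs("x", a=(1.0, 0.01)), "y": recs("y", a=(1.0, 0.0005)),
                  "xy": recs("xy", a=(1.0, 0.5))}
        out = flag_significant(self._table(z=0.0), tables)
        assert bool(out["tier_a"][0])
        assert not bool(out["tier_b"][0])

    def test_tier_b_fold_change_gate(self):
        # q passes everywhere but |lfc| = 1.5 <= 2 -> tier B false despite |z| = 3
        tables = {c: recs(c, a=(1.5, 0.0005)) for c in ("x", "y", "xy")}
        out = flag_significant(self._table(z=3.0), tables)
        assert not bool(out["tier_b"][0])

    def test_tier_b_requires_extreme_z(self):
        tables = {c: recs(c, a=(3.0, 0.0005)) for c in ("x", "y", "xy")}
        assert bool(flag_significant(self._table(z=3.0), tables)["tier_b"][0])
        assert not bool(flag_significant(self._table(z=1.9), tables)["tier_b"][0])

    def test_absent_gene_is_nonsignificant(self):
        tables = {"x": recs("x", b=(3.0, 0.0005))}
        out = flag_significant(self._table(z=3.0), tables)
        assert not bool(out["tier_a"][0])


class TestSignBalance:
    def test_balanced(self):
        p, npos, nneg = sign_balance([1] * 5 + [-1] * 5)
        assert p == pytest.approx(1.0)

    def test_nine_vs_one_enumeration(self):
        # two-sided exact binomial: 2 * P(X >= 9 | n=10, p=.5) = 22/1024
        p, npos, nneg = sign_balance([1] * 9 + [-1])
        assert p == pytest.approx(22 / 1024, rel=1e-9)

    def test_zero_vs_ten_enumeration(self):
        p, npos, nneg = sign_balance([-1] * 10)
        assert p == pytest.approx(2 / 1024, rel=1e-9)
        assert npos == 0 and nneg == 10

    def test_no_qualifying_genes(self):
        p, npos, nneg = sign_balance([0.0, 0.0])
        assert math.isnan(p)

    def test_power_at_two_to_one_imbalance(self, rng):
        hits = 0
        for _ in range(100):
            n_pos = rng.binomial(150, 2 / 3)
            eps = [1] * n_pos + [-1] * (150 - n_pos)
            p, _, _ = sign_balance(eps)
            hits += p < 0.05
        assert hits >= 90


class TestMoments:
    def test_symmetric_vector_has_zero_skew(self):
        m = moments([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_two_point_vector_at_kurtosis_floor(self):
        m = moments([-1.0, 1.0, -1.0, 1.0])
        assert m.kurtosis == pytest.approx(1.0, rel=1e-12)

    def test_pearson_lower_bound(self, rng):
        for _ in range(20):
            m = moments(rng.normal(0, 1, 30))
            assert m.kurtosis >= m.skewness**2 + 1 - 1e-9

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(10**5)
        m = moments(x)
        assert abs(m.skewness) < 0.03
        assert abs(m.kurtosis - 3.0) < 0.06

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            moments([1.0, 1.0, 1.0, 1.0])


class TestBuildTable:
    def test_genes_missing_a_contrast_are_skipped(self):
        t = build_epistasis_table(
            recs("x", a=(1.0, 0.5), b=(1.0, 0.5), c=(0.0, 0.5), d=(1.0, 0.5)),
            recs("y", a=(2.0, 0.5), b=(0.0, 0.5), c=(1.0, 0.5), d=(1.0, 0.5)),
            recs("xy", a=(4.0, 0.5), b=(1.0, 0.5), c=(2.0, 0.5), e=(1.0, 0.5)),
            "d1")
        assert set(t["gene"]) == {"a", "b", "c"}
        row = t.set_index("gene").loc["a"]
        assert row["epsilon_exp"] == pytest.approx(1.0)


class TestGeneSetSummary:
    @staticmethod
    def _table(eps, flags, genes=None):
        genes = genes or [f"g{i}" for i in range(len(eps))]
        return pd.DataFrame({"gene": genes, "double_id": "d",
                             "epsilon_exp": eps, "tier_a": flags,
                             "tier_b": flags})

    def test_whole_genome_set_is_degenerate(self):
        t = self._table([0.1, -0.2, 0.3, 0.5], [True] * 4)
        s = geneset_summary(t, t["gene"], "all")
        assert math.isnan(s.wilcoxon_p)

    def test_empty_intersection_rejected(self):
        t = self._table([0.1, -0.2], [True, True])
        with pytest.raises(ValueError, match="nope"):
            geneset_summary(t, ["zz"], "nope")

    def test_wilcoxon_null_calibration(self, rng):
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            eps = rng.normal(0, 1, 120)
            t = self._table(list(eps), [False] * 120)
            s = geneset_summary(t, [f"g{i}" for i in range(30)], "s")
            rejections += s.wilcoxon_p < 0.05
        rate = rejections / n_sim
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_f_test_power_on_variance_ratio(self, rng):
        hits = 0
        for _ in range(50):
            in_set = rng.normal(0, 2.0, 200)   # variance 4
            out_set = rng.normal(0, 1.0, 200)  # variance 1
            eps = np.concatenate([in_set, out_set])
            t = self._table(list(eps), [False] * 400)
            s = geneset_summary(t, [f"g{i}" for i in range(200)], "s")
            hits += s.f_test_p < 0.01
        assert hits >= 50 * 0.99

    def test_sign_counts_within_set(self):
        t = self._table([2.0, -1.0, 1.5, 0.5], [True, True, True, False])
        s = geneset_summary(t, ["g0", "g1", "g2"], "s")
        assert s.n_in_set == 3 and s.n_sig_epistatic == 3
        assert s.n_pos == 2 and s.n_neg == 1


class TestTierBRecovery:
    def test_planted_epistatic_genes_recovered(self, counts_bundle):
        """Planted |epsilon| = 2 genes pass the full tier-B gate at n=4."""
        from epinet.de import normalize, simple_de
        cm, truth = counts_bundle
        norm = normalize(cm.counts)
        meta = cm.sample_meta
        def grp(g):
            return list(meta[(meta.genotype == g) & (meta.temperature == 42.2)].index)
        anc42 = grp("ancestor")
        d = "rho_A43T+rpoB_I572F"
        rho, rpob = d.split("+")
        tabs = {f"{g}_vs_anc42": simple_de(norm, anc42, grp(g), f"{g}_vs_anc42")
                for g in (rho, rpob, d)}
        table = build_epistasis_table(tabs[f"{rho}_vs_anc42"],
                                      tabs[f"{rpob}_vs_anc42"],
                                      tabs[f"{d}_vs_anc42"], d)
        table = flag_significant(table, tabs)
        planted = {g for g, v in truth.true_epsilon_exp[d].items() if v != 0}
        genes = set(table["gene"])
        flagged = set(table.loc[table["tier_b"], "gene"])
        recall = len(flagged & planted) / len(planted & genes)
        false_rate = len(flagged - planted) / len(genes - planted)
        assert recall >= 0.90
        assert false_rate <= 0.05


class TestGeneSetIO:
    def test_plain_list(self, tmp_path):
        p = tmp_path / "hs.txt"
        p.write_text("geneA\ngeneB\n\n")
        assert read_gene_set(p) == {"hs": ["geneA", "geneB"]}

    def test_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("s1\tdesc\ta\tb\ns2\tdesc\tc\n")
        sets = read_gene_set(p)
        assert sets == {"s1": ["a", "b"], "s2": ["c"]}
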