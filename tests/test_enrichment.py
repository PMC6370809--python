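import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysoflux.enrichment import (
    ddct_relative_expression,
    fisher_enrich,
    intersect_sets,
    zscore_composite,
)
from lysoflux.io_core import ExpressionMatrix, GeneSet, SampleAnnotation
from lysoflux.synthetic import CountSimSpec, simulate_counts


def hypergeom_tail_exact(N, K, n, k):
    """Exact rational upper tail P(X >= k) via binomial coefficients."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return acc


class TestIntersectSets:
    def test_worked_partition(self):
        a = GeneSet("A", "", ("a", "b", "c"))
        b = GeneSet("B", "", ("b", "c", "d"))
        out = intersect_sets(a, b)
        assert out.both == ("b", "c")
        assert out.only_a == ("a",)
        assert out.only_b == ("d",)
        assert out.counts == (1, 2, 1)

    def test_disjoint_sets(self):
        out = intersect_sets(GeneSet("A", "", ("x",)), GeneSet("B", "", ("y",)))
        assert out.both == ()

    def test_identical_sets(self):
        a = GeneSet("A", "", ("p", "q"))
        out = intersect_sets(a, GeneSet("B", "", ("p", "q")))
        assert out.both == ("p", "q")
        assert out.only_a == () and out.only_b == ()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
        st.sets(st.sampled_from("abcdefgh"), min_size=1),
    )
    def test_commutative_up_to_side_swap(self, xs, ys):
        a, b = GeneSet("A", "", tuple(sorted(xs))), GeneSet("B", "", tuple(sorted(ys)))
        ab, ba = intersect_sets(a, b), intersect_sets(b, a)
        assert set(ab.both) == set(ba.both)
        assert set(ab.only_a) == set(ba.only_b)
        # parts are disjoint and cover the union
        parts = set(ab.only_a) | set(ab.both) | set(ab.only_b)
        assert parts == xs | ys
        assert not (set(ab.only_a) & set(ab.both))


class TestZscoreComposite:
    def test_rows_standardized_by_construction(self, toy_counts, lyso_set):
        matrix, ann = toy_counts
        table, _ = zscore_composite(matrix, lyso_set, ann)
        vals = matrix.values.loc[["Ctsb", "Ctss", "Acp5"]].to_numpy(dtype=float)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)
        np.testing.assert_allclose(table["score"], z.mean(axis=0), atol=1e-9)

    def test_planted_shift_detected(self):
        m, ann, truth = simulate_counts(
            CountSimSpec(
                n_genes=300,
                samples_per_group=10,
                planted_degs=tuple((i, 1.0) for i in range(20)),
                seed=3,
            )
        )
        gs = GeneSet("SET", "", tuple(truth["gene_id"]))
        table, p = zscore_composite(m, gs, ann)
        med = table.groupby("group_label")["score"].median()
        assert med["obese"] > med["lean"]
        assert p < 0.05

    def test_null_calibration(self):
        """Same-distribution groups: ~5% of repeats reach p < 0.05."""
        hits = 0
        reps = 100
        for seed in range(reps):
            m, ann, _ = simulate_counts(
                CountSimSpec(n_genes=60, samples_per_group=8, seed=1000 + seed)
            )
            gs = GeneSet("S", "", tuple(m.gene_ids[:15]))
            _, p = zscore_composite(m, gs, ann)
            hits += p < 0.05
        assert hits / reps <= 0.11  # 3 binomial sd above nominal 0.05

    def test_zero_variance_genes_excluded(self):
        df = pd.DataFrame(
            [[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["const", "g1", "g2"],
            columns=["a1", "a2", "b1", "b2"],
        )
        m = ExpressionMatrix(df, "counts")
        ann = SampleAnnotation.from_groups({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        table, _ = zscore_composite(m, GeneSet("S", "", ("const", "g1", "g2")), ann)
        assert len(table) == 4  # one score per sample, constant gene dropped

    def test_too_few_usable_genes_rejected(self, toy_counts):
        matrix, ann = toy_counts
        with pytest.raises(ValueError, match="at least 2"):
            zscore_composite(matrix, GeneSet("S", "", ("Ctsb",)), ann)

    def test_mannwhitney_invariant_to_monotone_transform(self):
        m, ann, _ = simulate_counts(CountSimSpec(n_genes=50, samples_per_group=6, seed=9))
        gs = GeneSet("S", "", tuple(m.gene_ids[:10]))
        _, p1 = zscore_composite(m, gs, ann)
        cubed = ExpressionMatrix(m.values.astype(float) ** 3, "log2")
        # note: z-scores differ after transform, so compare MW on identical scores
        table, _ = zscore_composite(m, gs, ann)
        from scipy.stats import mannwhitneyu

        a = table.loc[table["group_label"] == "lean", "score"]
        b = table.loc[table["group_label"] == "obese", "score"]
        p_mono = mannwhitneyu(np.exp(b), np.exp(a), alternative="two-sided",
                              method="asymptotic")[1]
        assert p1 == pytest.approx(p_mono, rel=1e-9)


class TestFisherEnrich:
    def test_full_overlap_small_universe(self):
        universe = GeneSet("U", "", tuple(f"g{i}" for i in range(10)))
        term = GeneSet("T", "", ("g0", "g1", "g2"))
        query = GeneSet("Q", "", ("g0", "g1", "g2"))
        out = fisher_enrich(query, [term], universe)
        assert out["p_value"].iloc[0] == pytest.approx(1 / comb(10, 3), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = GeneSet("U", "", tuple(f"g{i}" for i in range(8)))
        term = GeneSet("T", "", ("g0", "g1"))
        query = GeneSet("Q", "", ("g5", "g6"))
        out = fisher_enrich(query, [term], universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_partial_overlap_hand_value(self):
        # N=4, K=2, n=2, k=1 → 1 − P(X=0) = 1 − 1/6
        universe = GeneSet("U", "", ("a", "b", "c", "d"))
        term = GeneSet("T", "", ("a", "b"))
        query = GeneSet("Q", "", ("a", "c"))
        out = fisher_enrich(query, [term], universe)
        assert out["p_value"].iloc[0] == pytest.approx(5 / 6, rel=1e-9)

    def test_matches_exact_rational_tail_for_all_small_cases(self):
        """Upper-tail p equals the exact hypergeometric sum for all N ≤ 12."""
        from scipy.stats import hypergeom

        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        expected = float(hypergeom_tail_exact(N, K, n, k))
                        got = float(hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_brute_force_draw_enumeration(self):
        """p equals the fraction of n-draws with ≥ k term genes, enumerated."""
        N, K, n = 8, 3, 4
        universe = GeneSet("U", "", tuple(f"g{i}" for i in range(N)))
        term = GeneSet("T", "", tuple(f"g{i}" for i in range(K)))
        query = GeneSet("Q", "", ("g0", "g1", "g4", "g5"))  # k = 2
        out = fisher_enrich(query, [term], universe)
        term_set = set(term.members)
        draws = list(itertools.combinations(universe.members, n))
        frac = sum(len(set(d) & term_set) >= 2 for d in draws) / len(draws)
        assert out["p_value"].iloc[0] == pytest.approx(frac, rel=1e-12)

    def test_query_genes_outside_universe_dropped(self, caplog):
        universe = GeneSet("U", "", ("a", "b", "c", "d"))
        term = GeneSet("T", "", ("a", "b"))
        query = GeneSet("Q", "", ("a", "zzz"))
        with caplog.at_level("WARNING"):
            out = fisher_enrich(query, [term], universe)
        assert out["n"].iloc[0] == 1
        assert any("outside the universe" in r.message for r in caplog.records)

    def test_disjoint_universe_yields_trivial_p(self):
        out = fisher_enrich(
            GeneSet("Q", "", ("a",)),
            [GeneSet("T", "", ("a",))],
            GeneSet("U", "", ("x", "y")),
        )
        assert out["n"].iloc[0] == 0
        assert out["p_value"].iloc[0] == pytest.approx(1.0)


class TestDdct:
    def make_inputs(self):
        ct = pd.DataFrame(
            [
                ("ctrl1", "36b4", 15.0), ("ctrl1", "Ctsb", 22.0),
                ("ctrl2", "36b4", 15.0), ("ctrl2", "Ctsb", 22.0),
                ("tnf1", "36b4", 15.0), ("tnf1", "Ctsb", 20.0),
            ],
            columns=["sample_id", "gene", "ct"],
        )
        ann = SampleAnnotation.from_groups(
            {"ctrl1": "control", "ctrl2": "control", "tnf1": "tnf"}
        )
        return ct, ann

    def test_hand_computed_relative_expression(self):
        ct, ann = self.make_inputs()
        out = ddct_relative_expression(ct, "36b4", "control", ann)
        row = out[(out["sample_id"] == "tnf1")].iloc[0]
        assert row["delta_delta_ct"] == pytest.approx(-2.0)
        assert row["rel_expr"] == pytest.approx(4.0)

    def test_control_group_centred_at_unity(self):
        ct, ann = self.make_inputs()
        out = ddct_relative_expression(ct, "36b4", "control", ann)
        ctrl = out[out["group_label"] == "control"]
        assert np.log2(ctrl["rel_expr"]).mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_reference_ct_names_sample(self):
        ct, ann = self.make_inputs()
        ct = ct[~((ct["sample_id"] == "tnf1") & (ct["gene"] == "36b4"))]
        with pytest.raises(ValueError, match="tnf1"):
            ddct_relative_expression(ct, "36b4", "control", ann)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-5, 5))
    def test_per_sample_ct_shift_cancels(self, shift):
        """Adding a constant to every CT of one sample leaves rel_expr unchanged."""
        ct, ann = self.make_inputs()
        out1 = ddct_relative_expression(ct, "36b4", "control", ann)
        shifted = ct.copy()
        shifted.loc[shifted["sample_id"] == "tnf1", "ct"] += shift
        out2 = ddct_relative_expression(shifted, "36b4", "control", ann)
        np.testing.assert_allclose(out1["rel_expr"], out2["rel_expr"], rtol=1e-9)
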