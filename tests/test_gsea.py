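import numpy as np
import pandas as pd
import pytest

from lysoflux.gsea import (
    RankedList,
    enrichment_score,
    gsea_significance,
    gsea_table,
    rank_genes,
)
from lysoflux.io_core import ExpressionMatrix, GeneSet, SampleAnnotation
from lysoflux.synthetic import CountSimSpec, simulate_counts


def brute_force_running_sum(genes, metrics, members, p):
    """Direct loop re-derivation of the weighted running sum."""
    hits = [g in members for g in genes]
    n_hits = sum(hits)
    n_miss = len(genes) - n_hits
    total = sum(abs(m) ** p for g, m in zip(genes, metrics) if g in members)
    running, acc = [], 0.0
    for g, m in zip(genes, metrics):
        if g in members:
            acc += (abs(m) ** p) / total if total > 0 else 1.0 / n_hits
        else:
            acc -= 1.0 / n_miss
        running.append(acc)
    es = max(running, key=abs)
    return es, running


def ks_statistic(genes, members):
    """Two-sample KS distance between hit and miss position CDFs (unsigned)."""
    hit_pos = [i for i, g in enumerate(genes) if g in members]
    miss_pos = [i for i, g in enumerate(genes) if g not in members]
    best = 0.0
    for i in range(len(genes)):
        f_hit = sum(p <= i for p in hit_pos) / len(hit_pos)
        f_miss = sum(p <= i for p in miss_pos) / len(miss_pos)
        best = max(best, abs(f_hit - f_miss))
    return best


def two_group_matrix(vals, n_a, n_b, prefix=("a", "b")):
    vals = np.asarray(vals, float)
    cols = [f"{prefix[0]}{j}" for j in range(n_a)] + [f"{prefix[1]}{j}" for j in range(n_b)]
    m = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(len(vals))], columns=cols),
        "log2",
    )
    ann = SampleAnnotation.from_groups(
        {c: ("A" if c.startswith(prefix[0]) else "B") for c in cols}
    )
    return m, ann


class TestRankGenes:
    def test_shifted_gene_ranks_first_under_every_metric(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.1, size=(2, 6))
        vals[0, 3:] += 5.0  # gene g0 higher in group B
        m, ann = two_group_matrix(vals, 3, 3)
        for metric in ("signal_to_noise", "log2fc", "t_stat"):
            ranked = rank_genes(m, ann, metric=metric)
            assert ranked.gene_ids[0] == "g0"

    def test_group_swap_reverses_ranking(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 8))
        m, ann = two_group_matrix(vals, 4, 4)
        fwd = rank_genes(m, ann, group_a="A", group_b="B")
        rev = rank_genes(m, ann, group_a="B", group_b="A")
        np.testing.assert_allclose(
            sorted(fwd.metric_values), sorted(-np.asarray(rev.metric_values)), atol=1e-12
        )
        assert fwd.gene_ids == tuple(reversed(rev.gene_ids))

    def test_signal_to_noise_hand_table(self):
        vals = np.array(
            [
                [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
                [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
                [10.0, 8.0, 6.0, 2.0, 1.0, 0.0],
                [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
                [2.0, 2.0, 2.0, 8.0, 8.0, 8.0],
            ]
        )
        m, ann = two_group_matrix(vals, 3, 3)
        ranked = rank_genes(m, ann, metric="signal_to_noise")
        got = dict(zip(ranked.gene_ids, ranked.metric_values))
        # hand computation: (mean_B - mean_A) / (sd_A + sd_B), sd floored at 0.2|mean|
        assert got["g0"] == pytest.approx(4.0 / (1.0 + 1.2))  # B-side floor 0.2*6
        assert got["g1"] == pytest.approx(0.0 / (0.8 + 0.8))  # floor 0.2*4 on both sds
        assert got["g2"] == pytest.approx((1.0 - 8.0) / (2.0 + 1.0))
        assert got["g4"] == pytest.approx(6.0 / (0.4 + 1.6))  # sd floors 0.2*2, 0.2*8
        assert ranked.gene_ids[0] == "g4"

    def test_tie_broken_by_gene_id(self):
        vals = np.tile([1.0, 1.0, 2.0, 2.0], (3, 1))
        m, ann = two_group_matrix(vals, 2, 2)
        ranked = rank_genes(m, ann)
        assert ranked.gene_ids == ("g0", "g1", "g2")


class TestEnrichmentScore:
    def test_single_top_hit_unweighted(self):
        ranked = RankedList(("g1", "g2", "g3"), (3.0, 2.0, 1.0))
        es, running = enrichment_score(ranked, GeneSet("S", "", ("g1",)), 0.0)
        np.testing.assert_allclose(running, [1.0, 0.5, 0.0])
        assert es == 1.0

    def test_single_bottom_hit_unweighted(self):
        ranked = RankedList(("g1", "g2", "g3", "g4"), (3.0, 2.0, 1.0, 0.5))
        es, running = enrichment_score(ranked, GeneSet("S", "", ("g4",)), 0.0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert es == -1.0

    def test_set_covering_all_genes_degenerates_with_warning(self):
        ranked = RankedList(("g1", "g2"), (2.0, 1.0))
        with pytest.warns(UserWarning, match="whole ranked list"):
            es, _ = enrichment_score(ranked, GeneSet("S", "", ("g1", "g2")), 1.0)
        assert es == 1.0

    def test_running_sum_ends_at_zero_unweighted(self):
        rng = np.random.default_rng(2)
        genes = tuple(f"g{i}" for i in range(20))
        ranked = RankedList(genes, tuple(sorted(rng.normal(size=20), reverse=True)))
        _, running = enrichment_score(ranked, GeneSet("S", "", genes[3:8]), 0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_short_lists(self, weight_p, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        genes = tuple(f"g{i}" for i in range(n))
        metrics = tuple(sorted(rng.normal(size=n), reverse=True))
        ranked = RankedList(genes, metrics)
        size = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=size, replace=False))
        es, running = enrichment_score(ranked, GeneSet("S", "", tuple(sorted(members))), weight_p)
        es_bf, running_bf = brute_force_running_sum(genes, metrics, members, weight_p)
        np.testing.assert_allclose(running, running_bf, atol=1e-12)
        assert es == pytest.approx(es_bf, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_unweighted_es_equals_ks_statistic(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 11))
        genes = tuple(f"g{i}" for i in range(n))
        ranked = RankedList(genes, tuple(sorted(rng.normal(size=n), reverse=True)))
        size = int(rng.integers(1, n))
        members = set(rng.choice(genes, size=size, replace=False))
        es, _ = enrichment_score(ranked, GeneSet("S", "", tuple(sorted(members))), 0.0)
        assert abs(es) == pytest.approx(ks_statistic(genes, members), abs=1e-12)

    def test_no_overlap_rejected(self):
        ranked = RankedList(("g1", "g2"), (2.0, 1.0))
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(ranked, GeneSet("S", "", ("zz",)), 1.0)


class TestGseaSignificance:
    def test_p_lower_bound_is_add_one(self):
        m, ann, truth = simulate_counts(
            CountSimSpec(
                n_genes=200,
                samples_per_group=10,
                planted_degs=tuple((i, 3.0) for i in range(25)),
                seed=17,
            )
        )
        gs = GeneSet("P", "", tuple(truth["gene_id"]))
        recs = gsea_significance(m, ann, [gs], n_permutations=99, seed=17)
        assert recs[0].p_value >= 1 / 100
        assert recs[0].p_value == pytest.approx(1 / 100)

    def test_planted_shift_detected(self):
        m, ann, truth = simulate_counts(
            CountSimSpec(
                n_genes=500,
                samples_per_group=10,
                planted_degs=tuple((i, 1.0) for i in range(30)),
                seed=17,
            )
        )
        gs = GeneSet("P", "", tuple(truth["gene_id"]))
        recs = gsea_significance(m, ann, [gs], n_permutations=1000, seed=17)
        assert recs[0].nes > 0
        assert recs[0].p_value < 0.05

    def test_seeded_determinism(self):
        m, ann, _ = simulate_counts(CountSimSpec(n_genes=100, samples_per_group=8, seed=4))
        sets = [GeneSet("S", "", tuple(m.gene_ids[:12]))]
        r1 = gsea_significance(m, ann, sets, n_permutations=50, seed=21)
        r2 = gsea_significance(m, ann, sets, n_permutations=50, seed=21)
        assert r1[0].p_value == r2[0].p_value
        assert r1[0].nes == r2[0].nes

    def test_small_design_falls_back_to_gene_set_mode(self, caplog):
        m, ann, _ = simulate_counts(CountSimSpec(n_genes=50, samples_per_group=3, seed=5))
        sets = [GeneSet("S", "", tuple(m.gene_ids[:8]))]
        with caplog.at_level("WARNING"):
            recs = gsea_significance(m, ann, sets, n_permutations=20, seed=1, mode="phenotype")
        assert any("gene_set" in r.message for r in caplog.records)
        assert len(recs) == 1

    def test_null_p_values_not_anticonservative(self):
        """Random sets on null data: ≲5% reach p < 0.05."""
        m, ann, _ = simulate_counts(CountSimSpec(n_genes=400, samples_per_group=10, seed=5))
        rng = np.random.default_rng(7)
        sets = [
            GeneSet(f"S{i}", "", tuple(rng.choice(m.gene_ids, size=25, replace=False)))
            for i in range(50)
        ]
        recs = gsea_significance(m, ann, sets, n_permutations=200, seed=9)
        ps = np.array([r.p_value for r in recs])
        # binomial tolerance around 0.05 over 50 correlated sets
        assert (ps < 0.05).mean() <= 0.14
        table = gsea_table(recs)
        assert set(table.columns) >= {"set_name", "es", "nes", "p_value", "fdr"}
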