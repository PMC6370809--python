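"""Gene set enrichment analysis: ranking metric, weighted running-sum
enrichment score, and permutation significance.

Genes are ranked by a two-group metric (signal-to-noise by default, the
canonical choice); a set's enrichment score is the signed maximal deviation
of a running sum that increments at set members by |metric|^p (p = 1 default)
and decrements uniformly at non-members. Significance comes from a null ES
distribution built by permuting phenotype labels (or, for small designs,
sampling random same-size sets), with sign-matched normalization (NES) and
an add-one permutation p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import bh_fdr
from .io_core import ExpressionMatrix, GeneSet, SampleAnnotation

logger = logging.getLogger(__name__)

METRICS = ("signal_to_noise", "log2fc", "t_stat")


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken by gene id."""

    gene_ids: tuple[str, ...]
    metric_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if not np.isfinite(self.metric_values).all():
            raise ValueError("ranking metric contains non-finite values")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaRecord:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    n_hits: int
    running_sum: np.ndarray = field(repr=False)


def _metric_values(
    vals: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, metric: str, value_kind: str
) -> np.ndarray:
    """Per-gene two-group ranking metric, positive when higher in group B."""
    a, b = vals[:, idx_a], vals[:, idx_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    if metric == "signal_to_noise":
        sd_a = np.maximum.reduce(
            [a.std(axis=1, ddof=1), 0.2 * np.abs(mean_a), np.full(len(a), 1e-8)]
        )
        sd_b = np.maximum.reduce(
            [b.std(axis=1, ddof=1), 0.2 * np.abs(mean_b), np.full(len(b), 1e-8)]
        )
        return (mean_b - mean_a) / (sd_a + sd_b)
    if metric == "t_stat":
        na, nb = a.shape[1], b.shape[1]
        se = np.sqrt(
            np.maximum(a.var(axis=1, ddof=1), 1e-16) / na
            + np.maximum(b.var(axis=1, ddof=1), 1e-16) / nb
        )
        return (mean_b - mean_a) / se
    if metric == "log2fc":
        if value_kind == "log2":
            return mean_b - mean_a
        return np.log2((mean_b + 0.5) / (mean_a + 0.5))
    raise ValueError(f"metric must be one of {METRICS}")


def rank_genes(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    metric: str = "signal_to_noise",
    group_a: str | None = None,
    group_b: str | None = None,
) -> RankedList:
    """Rank genes by a two-group metric, descending (higher in B first)."""
    annotation.check_against(matrix)
    _, samples_a, _, samples_b = annotation.two_groups(group_a, group_b)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    vals = matrix.values.to_numpy(dtype=float)
    m = _metric_values(
        vals,
        np.array([col[s] for s in samples_a]),
        np.array([col[s] for s in samples_b]),
        metric,
        matrix.value_kind,
    )
    genes = np.asarray(matrix.gene_ids)
    # sort by metric descending, gene id ascending for deterministic ties
    order = np.lexsort((genes, -m))
    return RankedList(tuple(genes[order]), tuple(m[order]))


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov–Smirnov-style running sum and its signed extremum.

    Hits add |metric|^weight_p normalized to sum 1 over hits; misses subtract
    1/(N − |S|). The enrichment score is the running-sum entry of maximal
    absolute value. With weight_p = 0 the statistic reduces to the classical
    KS distance between hit and miss positions.
    """
    if weight_p < 0:
        raise ValueError("weight_p must be >= 0")
    members = gene_set.as_set()
    hits = np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranked list")
    N = len(ranked)
    if n_hits == N:
        warnings.warn(
            f"gene set {gene_set.name!r} covers the whole ranked list; ES degenerates to 1"
        )
        running = np.cumsum(np.full(N, 1.0 / N))
        return 1.0, running

    weights = np.abs(np.asarray(ranked.metric_values)) ** weight_p
    hit_weights = np.where(hits, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all hit metrics are exactly zero: fall back to equal steps
        hit_weights = hits.astype(float)
        total = float(n_hits)
    increments = hit_weights / total - (~hits) / (N - n_hits)
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es_phenotype(
    vals, idx_all, n_a, hit_masks, weight_p, metric, value_kind, genes, rng, n_perm
):
    """Null ES per set from label permutations (recomputes the ranking each time)."""
    null = np.empty((n_perm, len(hit_masks)))
    N = vals.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(idx_all)
        m = _metric_values(vals, perm[:n_a], perm[n_a:], metric, value_kind)
        order = np.lexsort((genes, -m))
        weights = np.abs(m[order]) ** weight_p
        for si, mask in enumerate(hit_masks):
            hits = mask[order]
            n_hits = hits.sum()
            hw = np.where(hits, weights, 0.0)
            total = hw.sum()
            if total == 0:
                hw, total = hits.astype(float), float(n_hits)
            running = np.cumsum(hw / total - (~hits) / (N - n_hits))
            null[b, si] = running[np.argmax(np.abs(running))]
    return null


def _null_es_geneset(ranked, set_sizes, weight_p, rng, n_perm):
    """Null ES per set size from random same-size sets on the fixed ranking."""
    N = len(ranked)
    weights_all = np.abs(np.asarray(ranked.metric_values)) ** weight_p
    null = np.empty((n_perm, len(set_sizes)))
    for b in range(n_perm):
        for si, size in enumerate(set_sizes):
            pick = rng.choice(N, size=size, replace=False)
            hits = np.zeros(N, bool)
            hits[pick] = True
            hw = np.where(hits, weights_all, 0.0)
            total = hw.sum()
            if total == 0:
                hw, total = hits.astype(float), float(size)
            running = np.cumsum(hw / total - (~hits) / (N - size))
            null[b, si] = running[np.argmax(np.abs(running))]
    return null


def gsea_significance(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    gene_sets: list[GeneSet],
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "auto",
    metric: str = "signal_to_noise",
    weight_p: float = 1.0,
    group_a: str | None = None,
    group_b: str | None = None,
) -> list[GseaRecord]:
    """Permutation GSEA over a collection of gene sets.

    ``mode``: 'phenotype' permutes group labels (requires ≥ 7 samples in
    total; 'auto' picks it when each group has ≥ 7 samples), 'gene_set'
    samples random same-size sets on the fixed ranking. NES divides ES by the
    mean |null ES| of matching sign; p is the add-one one-sided permutation
    tail; FDR is Benjamini–Hochberg across sets.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if mode not in ("auto", "phenotype", "gene_set"):
        raise ValueError("mode must be 'auto', 'phenotype' or 'gene_set'")
    annotation.check_against(matrix)
    _, samples_a, _, samples_b = annotation.two_groups(group_a, group_b)
    n_total = len(samples_a) + len(samples_b)
    if mode == "auto":
        mode = "phenotype" if min(len(samples_a), len(samples_b)) >= 7 else "gene_set"
    elif mode == "phenotype" and n_total < 7:
        logger.warning(
            "phenotype permutation with %d samples is unstable; falling back to gene_set mode",
            n_total,
        )
        mode = "gene_set"

    ranked = rank_genes(matrix, annotation, metric, group_a, group_b)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    usable_sets, es_obs, runnings, hit_masks, sizes = [], [], [], [], []
    for gs in gene_sets:
        members = gs.as_set() & set(matrix.gene_ids)
        if not members:
            logger.warning("gene set %r shares no genes with the matrix; skipped", gs.name)
            continue
        es, running = enrichment_score(ranked, gs, weight_p)
        mask = np.zeros(matrix.n_genes, bool)
        for g in members:
            mask[gene_pos[g]] = True
        usable_sets.append(gs)
        es_obs.append(es)
        runnings.append(running)
        hit_masks.append(mask)
        sizes.append(len(members))

    rng = np.random.default_rng(seed)
    if not usable_sets:
        return []
    if mode == "phenotype":
        col = {s: i for i, s in enumerate(matrix.sample_ids)}
        idx_all = np.array([col[s] for s in samples_a] + [col[s] for s in samples_b])
        null = _null_es_phenotype(
            matrix.values.to_numpy(dtype=float),
            idx_all,
            len(samples_a),
            hit_masks,
            weight_p,
            metric,
            matrix.value_kind,
            np.asarray(matrix.gene_ids),
            rng,
            n_permutations,
        )
    else:
        null = _null_es_geneset(ranked, sizes, weight_p, rng, n_permutations)

    records = []
    pvals = []
    for si, (gs, es) in enumerate(zip(usable_sets, es_obs)):
        col_null = null[:, si]
        same_sign = col_null[np.sign(col_null) == np.sign(es)] if es != 0 else col_null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(col_null).mean()
        nes = es / denom if denom > 0 else 0.0
        extreme = int((np.abs(col_null) >= abs(es)).sum())
        p = (1 + extreme) / (n_permutations + 1)
        pvals.append(p)
        records.append(GseaRecord(gs.name, es, float(nes), p, np.nan, sizes[si], runnings[si]))
    fdr = bh_fdr(np.asarray(pvals))
    for rec, q in zip(records, fdr):
        rec.fdr = float(q)
    return records


def gsea_table(records: list[GseaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in records],
            "es": [r.es for r in records],
            "nes": [r.nes for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "n_hits": [r.n_hits for r in records],
        }
    )
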