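"""Gene-set intersection, z-score composite scoring, hypergeometric term
enrichment, and ΔΔCT relative quantification.

These are the cross-sectional summaries of the analysis: which differential
genes fall in the lysosomal/autophagic focus set (Venn overlap), whether that
set is coordinately shifted between groups (per-gene z-scores averaged per
sample, compared by Mann–Whitney U), which annotation terms are
over-represented (one-sided hypergeometric, BH-corrected), and how qPCR CT
values convert to relative expression (2^−ΔΔCT against a reference gene and
a control group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io_core import ExpressionMatrix, GeneSet, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Exact partition of two gene sets into only-A / both / only-B."""

    set_a_name: str
    set_b_name: str
    only_a: tuple[str, ...]
    both: tuple[str, ...]
    only_b: tuple[str, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.both), len(self.only_b))

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "only_a") for g in self.only_a]
            + [(g, "both") for g in self.both]
            + [(g, "only_b") for g in self.only_b]
        )
        return pd.DataFrame(rows, columns=["gene_id", "part"])


def intersect_sets(a: GeneSet, b: GeneSet) -> OverlapResult:
    """Venn-style overlap of two gene sets (order within parts preserved from a/b)."""
    sa, sb = a.as_set(), b.as_set()
    return OverlapResult(
        set_a_name=a.name,
        set_b_name=b.name,
        only_a=tuple(g for g in a.members if g not in sb),
        both=tuple(g for g in a.members if g in sb),
        only_b=tuple(g for g in b.members if g not in sa),
    )


def zscore_composite(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    annotation: SampleAnnotation,
    group_a: str | None = None,
    group_b: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-sample mean z over a gene set, plus a two-sided Mann–Whitney p.

    Each set gene present in the matrix is standardized across samples
    (population sd); a sample's composite score is the mean standardized
    value over those genes. Zero-variance genes are excluded with a warning;
    at least two usable genes are required. Group scores are compared with
    the Mann–Whitney U test (normal approximation, tie-corrected).
    """
    annotation.check_against(matrix)
    label_a, samples_a, label_b, samples_b = annotation.two_groups(group_a, group_b)
    present = [g for g in gene_set.members if g in matrix.values.index]
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    usable = sd > 0
    if (~usable).any():
        dropped = [g for g, u in zip(present, usable) if not u]
        logger.warning("excluding %d zero-variance gene(s): %s", len(dropped), dropped)
    if usable.sum() < 2:
        raise ValueError(
            f"need at least 2 usable set genes in the matrix, found {int(usable.sum())}"
        )
    sub = sub[usable]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0, keepdims=True)
    scores = pd.Series(z.mean(axis=0), index=matrix.sample_ids, name="score")

    table = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group_label": annotation.table["group"].reindex(matrix.sample_ids).to_numpy(),
            "score": scores.to_numpy(),
        }
    )
    _, p = stats.mannwhitneyu(
        scores[samples_b], scores[samples_a], alternative="two-sided", method="asymptotic"
    )
    return table, float(p)


@dataclass(frozen=True)
class EnrichmentRecord:
    term_name: str
    k: int  # query ∩ term
    K: int  # term size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    fdr: float = np.nan


def fisher_enrich(
    query: GeneSet,
    terms: list[GeneSet],
    universe: GeneSet,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Term over-representation of a query set against a universe.

    Default is the one-sided over-representation tail
    p = P(X ≥ k) for X ~ Hypergeometric(N, K, n); ``two_sided`` switches to
    the two-sided Fisher exact test on the 2×2 table. Query genes outside the
    universe are dropped with a warning; each term is intersected with the
    universe. FDR is Benjamini–Hochberg across terms.
    """
    uni = universe.as_set()
    if not uni:
        raise ValueError("universe is empty")
    q = [g for g in query.members if g in uni]
    if len(q) < len(query.members):
        logger.warning(
            "%d query gene(s) outside the universe dropped", len(query.members) - len(q)
        )
    qset = set(q)
    N, n = len(uni), len(qset)
    rows = []
    for term in terms:
        tset = term.as_set() & uni
        K = len(tset)
        k = len(tset & qset)
        if two_sided:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term.name, k, K, n, N, min(max(p, np.finfo(float).tiny), 1.0)))
    out = pd.DataFrame(rows, columns=["term_name", "k", "K", "n", "N", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_group: str,
    annotation: SampleAnnotation,
) -> pd.DataFrame:
    """ΔΔCT relative quantification against a reference gene and control group.

    ``ct_table`` has columns (sample_id, gene, ct). For each sample and
    target gene: ΔCT = CT_target − CT_reference; ΔΔCT = ΔCT minus the mean
    ΔCT of the control group for that target; relative expression is
    2^−ΔΔCT, so the control group's geometric-mean relative expression is 1.
    """
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    wide = ct_table.pivot_table(index="sample_id", columns="gene", values="ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from CT table")
    missing_ref = wide.index[wide[reference_gene].isna()]
    if len(missing_ref):
        raise ValueError(
            f"sample(s) missing a CT for reference gene {reference_gene!r}: "
            f"{list(missing_ref)}"
        )
    groups = annotation.table["group"].astype(str)
    control_samples = [
        s for s in wide.index if s in groups.index and groups[s] == control_group
    ]
    if not control_samples:
        raise ValueError(f"control group {control_group!r} has no samples in the CT table")

    targets = [g for g in wide.columns if g != reference_gene]
    rows = []
    for target in targets:
        missing = wide.index[wide[target].isna()]
        if len(missing):
            raise ValueError(
                f"sample(s) missing a CT for target {target!r}: {list(missing)}"
            )
        delta_ct = wide[target] - wide[reference_gene]
        control_mean = delta_ct.loc[control_samples].mean()
        ddct = delta_ct - control_mean
        for sid in wide.index:
            rows.append(
                (
                    sid,
                    groups.get(sid, ""),
                    target,
                    delta_ct[sid],
                    ddct[sid],
                    2.0 ** (-ddct[sid]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group_label", "target_gene", "delta_ct", "delta_delta_ct", "rel_expr"],
    )
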