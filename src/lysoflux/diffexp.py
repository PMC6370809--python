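"""Two-group differential expression on counts with fold-change and FDR gates.

Counts are normalized by median-of-ratios size factors, tested per gene with
a negative-binomial Wald statistic (moment dispersion shrunk toward a
mean–dispersion trend), corrected by Benjamini–Hochberg, and classified
up/down/ns under configurable gates — the human adipose contrast uses
FC > 1.2 or < 0.833 at FDR < 0.2, the time-course pre-filter FC > 2 or
< 0.5 at p < 0.05.

A Welch t test on log2(normalized + 1) is available for log-intensity
inputs where the count model does not apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

#: FC/significance gates for the human two-group contrast.
HUMAN_GATES_KW = dict(fc_up=1.2, fc_down=0.833, alpha=0.2, alpha_kind="fdr")
#: Gates for the per-time-point pre-filter of the series data.
TIMECOURSE_GATES_KW = dict(fc_up=2.0, fc_down=0.5, alpha=0.05, alpha_kind="pvalue")


@dataclass(frozen=True)
class DEGGates:
    """Fold-change and significance gates for calling a gene up/down/ns."""

    fc_up: float = 1.2
    fc_down: float = 0.833
    alpha: float = 0.2
    alpha_kind: str = "fdr"

    def __post_init__(self) -> None:
        if not (self.fc_down < 1 < self.fc_up):
            raise ValueError("gates must satisfy fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_kind not in ("fdr", "pvalue"):
            raise ValueError("alpha_kind must be 'fdr' or 'pvalue'")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def normalize_median_of_ratios(
    counts: ExpressionMatrix, positive_subset: bool = False
) -> tuple[pd.Series, ExpressionMatrix]:
    """Median-of-ratios size factors and the normalized matrix.

    The size factor of sample j is the median, over genes with a positive
    geometric mean, of count_gj divided by that gene's geometric mean across
    samples. With ``positive_subset`` the per-gene geometric mean and the
    ratios are taken over positive counts only (for matrices where no gene
    is positive in every sample).
    """
    if counts.value_kind != "counts":
        raise ValueError("median-of-ratios normalization expects a counts matrix")
    vals = counts.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log(vals)
    if positive_subset:
        masked = np.where(vals > 0, logv, np.nan)
        log_gm = np.nanmean(masked, axis=1)
        usable = ~np.isnan(log_gm)
    else:
        usable = (vals > 0).all(axis=1)
        log_gm = np.where(usable, logv.mean(axis=1), np.nan)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; re-run with "
            "positive_subset=True (config: normalization.positive_subset)"
        )
    log_ratios = logv[usable] - log_gm[usable, None]
    if positive_subset:
        log_ratios = np.where(vals[usable] > 0, log_ratios, np.nan)
        log_sf = np.nanmedian(log_ratios, axis=0)
    else:
        log_sf = np.median(log_ratios, axis=0)
    size_factors = pd.Series(np.exp(log_sf), index=counts.sample_ids, name="size_factor")
    normalized = ExpressionMatrix(
        counts.values / size_factors.to_numpy()[None, :], value_kind="log2"
    )
    # value_kind "log2" here only marks the matrix as real-valued; the scale
    # is linear normalized counts.
    return size_factors, normalized


def _moment_dispersions(
    norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, shrink_weight: float
) -> np.ndarray:
    """Per-gene NB dispersion: method of moments shrunk toward a log-linear trend."""
    floor = 1e-8
    a, b = norm[:, idx_a], norm[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    mu = norm.mean(axis=1)
    mu_safe = np.maximum(mu, floor)
    raw = np.maximum((pooled_var - mu_safe) / mu_safe**2, floor)

    informative = raw > floor
    if informative.sum() >= 2 and np.ptp(np.log(mu_safe[informative])) > 0:
        slope, intercept = np.polyfit(
            np.log(mu_safe[informative]), np.log(raw[informative]), 1
        )
        trend = np.exp(intercept + slope * np.log(mu_safe))
    else:
        trend = np.full_like(raw, max(np.exp(np.log(raw).mean()), floor))
    trend = np.maximum(trend, floor)
    return np.exp(
        (1 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )


def test_differential(
    counts: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str | None = None,
    group_b: str | None = None,
    method: str = "nb_wald",
    min_mean: float = 1.0,
    shrink_weight: float = 0.5,
    pseudocount: float = 0.5,
    positive_subset: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group test; returns a DEG table with status unset ('ns').

    ``nb_wald``: negative-binomial Wald test on the log fold change of
    median-of-ratios-normalized group means, with per-gene moment dispersion
    shrunk toward a log-linear mean–dispersion trend and a t reference on
    n_A + n_B − 2 degrees of freedom. ``welch_log``: Welch t test on
    log2(normalized + 1), for log-intensity-like data.

    Fold change is (mean_B + pseudocount) / (mean_A + pseudocount); genes
    with mean normalized count below ``min_mean`` are dropped before testing.
    """
    if method not in ("nb_wald", "welch_log"):
        raise ValueError("method must be 'nb_wald' or 'welch_log'")
    annotation.check_against(counts)
    label_a, samples_a, label_b, samples_b = annotation.two_groups(group_a, group_b)

    if counts.value_kind == "counts":
        _, normalized = normalize_median_of_ratios(counts, positive_subset=positive_subset)
        norm_df = normalized.values
    else:
        norm_df = counts.values
    col_idx = {s: i for i, s in enumerate(norm_df.columns)}
    idx_a = np.array([col_idx[s] for s in samples_a])
    idx_b = np.array([col_idx[s] for s in samples_b])
    norm = norm_df.to_numpy(dtype=float)

    keep = norm.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("no gene passes the low-count filter")
    norm = norm[keep]
    gene_ids = np.asarray(counts.gene_ids)[keep]

    na, nb = len(idx_a), len(idx_b)
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    log2_fc = np.log2(fc)

    if method == "nb_wald":
        disp = _moment_dispersions(norm, idx_a, idx_b, shrink_weight)
        mu_a = mean_a + pseudocount
        mu_b = mean_b + pseudocount
        var_a = mu_a + disp * mu_a**2
        var_b = mu_b + disp * mu_b**2
        se_log = np.sqrt(var_a / (na * mu_a**2) + var_b / (nb * mu_b**2))
        stat = np.log(fc) / se_log
        df = na + nb - 2
        p = 2 * stats.t.sf(np.abs(stat), df)
    else:
        la = np.log2(norm[:, idx_a] + 1)
        lb = np.log2(norm[:, idx_b] + 1)
        stat, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)

    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": norm.mean(axis=1),
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": bh_fdr(p),
            "status": "ns",
        }
    )


def classify_deg(records: pd.DataFrame, gates: DEGGates) -> pd.DataFrame:
    """Set status: up iff FC > fc_up and significance < alpha; down likewise.

    Fold-change comparisons are strict, as is the significance ceiling
    (matching the printed "FDR < 0.2" direction).
    """
    sig_col = "fdr" if gates.alpha_kind == "fdr" else "p_value"
    out = records.copy()
    sig = out[sig_col] < gates.alpha
    out["status"] = np.select(
        [sig & (out["fold_change"] > gates.fc_up), sig & (out["fold_change"] < gates.fc_down)],
        ["up", "down"],
        default="ns",
    )
    return out


def deg_gene_ids(records: pd.DataFrame, direction: str = "both") -> list[str]:
    """Gene ids called up, down, or both (any non-ns)."""
    if direction == "both":
        mask = records["status"] != "ns"
    elif direction in ("up", "down"):
        mask = records["status"] == direction
    else:
        raise ValueError("direction must be 'up', 'down' or 'both'")
    return records.loc[mask, "gene_id"].tolist()
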