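"""Short-time-series profile clustering: enumerate model profiles, assign
genes, and test profile over-representation against a per-gene permutation
null.

A model profile for T ordered time points is a vector of T−1 unit changes,
each in {−c, …, +c}, excluding the all-flat vector; its template is the
cumulative sum anchored at 0. For T = 4 and c = 1 this yields 3³ − 1 = 26
profiles. Genes are assigned to the nearest template (Euclidean distance
after anchoring at the first time point), and a profile is significant when
it captures more genes than expected under random time orderings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelProfile:
    """One enumerated expression tendency: unit changes and their template."""

    profile_id: int
    change_vector: tuple[int, ...]
    template: tuple[int, ...]


def enumerate_profiles(n_timepoints: int, unit_change_bound: int = 1) -> list[ModelProfile]:
    """Enumerate all (2c+1)^(T−1) − 1 non-flat model profiles.

    Profiles are ordered canonically: lexicographic over change vectors with
    entries ordered −c < … < +c; profile_id is the rank in that order.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if unit_change_bound < 1:
        raise ValueError("unit change bound must be >= 1")
    steps = range(-unit_change_bound, unit_change_bound + 1)
    profiles: list[ModelProfile] = []
    pid = 0
    for change in itertools.product(steps, repeat=n_timepoints - 1):
        if all(s == 0 for s in change):
            continue
        template = (0, *itertools.accumulate(change))
        profiles.append(ModelProfile(pid, change, template))
        pid += 1
    return profiles


def profiles_table(profiles: list[ModelProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "change_vector": [",".join(map(str, p.change_vector)) for p in profiles],
            "template": [",".join(map(str, p.template)) for p in profiles],
        }
    )


def average_replicates(
    series: ExpressionMatrix,
    annotation: SampleAnnotation,
    agg: str = "mean",
) -> pd.DataFrame:
    """Collapse replicate columns to one column per time point, in declared order."""
    if not annotation.time_order:
        raise ValueError("annotation must declare a time order")
    annotation.check_against(series)
    tp = annotation.table["time_point"].dropna().astype(str)
    cols_by_tp: dict[str, list[str]] = {t: [] for t in annotation.time_order}
    for sid, t in tp.items():
        if sid in series.values.columns:
            cols_by_tp[t].append(sid)
    missing = [t for t, cols in cols_by_tp.items() if not cols]
    if missing:
        raise ValueError(f"no samples for time point(s) {missing}")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    out = {}
    for t, cols in cols_by_tp.items():
        block = series.values[cols]
        out[t] = block.mean(axis=1) if agg == "mean" else block.median(axis=1)
    return pd.DataFrame(out, index=series.values.index)


def _distance_matrix(
    anchored: np.ndarray, templates: np.ndarray, step_size: float
) -> np.ndarray:
    """Euclidean distances, genes × profiles."""
    diff = anchored[:, None, :] - step_size * templates[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def assign_profiles(
    series: ExpressionMatrix,
    annotation: SampleAnnotation,
    profiles: list[ModelProfile],
    step_size: float = 1.0,
    agg: str = "mean",
) -> pd.DataFrame:
    """Assign each gene to its nearest model profile.

    Each gene's replicate-averaged series is anchored (first time point
    subtracted) and compared with ``step_size`` times every template by
    Euclidean distance; ties go to the lowest profile_id.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    averaged = average_replicates(series, annotation, agg=agg)
    T = averaged.shape[1]
    templates = np.array([p.template for p in profiles], dtype=float)
    if templates.shape[1] != T:
        raise ValueError(
            f"profile universe built for {templates.shape[1]} time points, "
            f"series has {T}"
        )
    vals = averaged.to_numpy(dtype=float)
    anchored = vals - vals[:, [0]]
    dist = _distance_matrix(anchored, templates, step_size)
    best = dist.argmin(axis=1)  # argmin returns the first (lowest-id) minimum
    return pd.DataFrame(
        {
            "gene_id": averaged.index,
            "profile_id": [profiles[b].profile_id for b in best],
            "distance": dist[np.arange(len(best)), best],
        }
    )


def timecourse_prefilter(
    series: ExpressionMatrix,
    annotation: SampleAnnotation,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
) -> list[str]:
    """Genes responsive at any non-baseline time point under FC and p gates.

    For each later time point the log2 fold change versus the first time
    point is the difference of replicate means (the series is on the log2
    scale); significance is a Welch t test across replicates. With a single
    replicate per time point only the fold-change gate applies. A gene is
    kept if any time point passes FC > fc_up or FC < fc_down together with
    p < alpha.
    """
    averaged = average_replicates(series, annotation, agg="mean")
    tp = annotation.table["time_point"].dropna().astype(str)
    cols_by_tp = {
        t: [s for s in series.sample_ids if tp.get(s) == t] for t in annotation.time_order
    }
    base = annotation.time_order[0]
    keep = np.zeros(series.n_genes, dtype=bool)
    lfc_up, lfc_down = np.log2(fc_up), np.log2(fc_down)
    base_block = series.values[cols_by_tp[base]].to_numpy(dtype=float)
    for t in annotation.time_order[1:]:
        block = series.values[cols_by_tp[t]].to_numpy(dtype=float)
        lfc = averaged[t].to_numpy() - averaged[base].to_numpy()
        if base_block.shape[1] >= 2 and block.shape[1] >= 2:
            _, p = stats.ttest_ind(block, base_block, axis=1, equal_var=False)
            p = np.where(np.isnan(p), 1.0, p)
        else:
            p = np.zeros(series.n_genes)  # no replication: FC gate only
        keep |= ((lfc > lfc_up) | (lfc < lfc_down)) & (p < alpha)
    return [g for g, k in zip(series.gene_ids, keep) if k]


def profile_significance(
    assignments: pd.DataFrame,
    series: ExpressionMatrix,
    annotation: SampleAnnotation,
    profiles: list[ModelProfile],
    n_permutations: int = 200,
    seed: int = 0,
    step_size: float = 1.0,
    agg: str = "mean",
    method: str = "binomial",
) -> pd.DataFrame:
    """Test each profile for capturing more genes than chance.

    The null reassigns every gene after independently permuting its time
    order (re-anchored each round); ``expected_n`` is the mean assigned count
    over permutations. Default significance is the one-sided binomial tail
    P(X ≥ observed) with success probability expected_n / n_genes;
    ``method='fisher2x2'`` instead builds a 2×2 table of observed vs rounded
    expected counts and applies a one-sided Fisher exact test. FDR is
    Benjamini–Hochberg across profiles.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if method not in ("binomial", "fisher2x2"):
        raise ValueError("method must be 'binomial' or 'fisher2x2'")
    pids = [p.profile_id for p in profiles]
    if assignments.empty:
        return pd.DataFrame(
            columns=["profile_id", "observed_n", "expected_n", "p_value", "fdr"]
        )
    averaged = average_replicates(series, annotation, agg=agg)
    vals = averaged.to_numpy(dtype=float)
    n_genes, T = vals.shape
    templates = np.array([p.template for p in profiles], dtype=float)

    observed = (
        assignments["profile_id"].value_counts().reindex(pids, fill_value=0).to_numpy()
    )

    rng = np.random.default_rng(seed)
    counts = np.zeros((n_permutations, len(profiles)))
    for b in range(n_permutations):
        permuted = rng.permuted(vals, axis=1)
        anchored = permuted - permuted[:, [0]]
        best = _distance_matrix(anchored, templates, step_size).argmin(axis=1)
        counts[b] = np.bincount(best, minlength=len(profiles))
    expected = counts.mean(axis=0)

    from .diffexp import bh_fdr  # local import to avoid a module cycle

    pvals = np.empty(len(profiles))
    for i, (obs, exp) in enumerate(zip(observed, expected)):
        if method == "binomial":
            p0 = min(max(exp / n_genes, 0.0), 1.0)
            pvals[i] = stats.binom.sf(obs - 1, n_genes, p0) if p0 > 0 else (
                1.0 if obs == 0 else 1.0 / (n_permutations + 1)
            )
        else:
            exp_r = int(round(exp))
            table = [[obs, n_genes - obs], [exp_r, n_genes - exp_r]]
            pvals[i] = stats.fisher_exact(table, alternative="greater")[1]
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "profile_id": pids,
            "observed_n": observed,
            "expected_n": expected,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
        }
    )
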