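"""Seeded generators for inputs with the statistical structure each stage assumes.

Three generators cover the three data shapes of the analysis:

* negative-binomial count matrices with planted fold-change genes in one of
  two groups (lean/obese-style contrast),
* log2 time-course matrices with genes planted into enumerated model
  profiles plus Gaussian noise (TNFα series-style),
* a single-latent-factor co-expression matrix with a planted module whose
  designated hub carries the largest loading.

Every generator is a pure function of its spec (including the seed) and
returns a ground-truth table sufficient to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, SampleAnnotation
from .profiles import ModelProfile, enumerate_profiles

DEFAULT_TIMEPOINTS = ("0h", "2h", "24h", "6d")


class SimSpecError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class CountSimSpec:
    """Two-group negative-binomial count simulation.

    Variance model: var = mu + dispersion * mu^2 (dispersion 0 is Poisson).
    ``planted_degs`` maps gene indices to log2 fold changes applied to the
    mean of group B. ``library_factor_range`` draws per-sample library-size
    factors log-uniformly; ``None`` fixes all factors at 1.
    """

    n_genes: int = 2000
    samples_per_group: int = 10
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    planted_degs: tuple[tuple[int, float], ...] = ()
    library_factor_range: tuple[float, float] | None = (0.7, 1.4)
    group_labels: tuple[str, str] = ("lean", "obese")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.samples_per_group < 1:
            raise SimSpecError("n_genes and samples_per_group must be positive")
        if self.baseline_mean <= 0:
            raise SimSpecError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise SimSpecError("dispersion must be non-negative")
        idx = [i for i, _ in self.planted_degs]
        if len(set(idx)) != len(idx):
            raise SimSpecError("planted gene indices must be unique")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise SimSpecError("planted gene index out of range")
        if self.library_factor_range is not None:
            lo, hi = self.library_factor_range
            if not (0 < lo <= hi):
                raise SimSpecError("library_factor_range must satisfy 0 < lo <= hi")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + disp*mu^2; Poisson when disp == 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion  # NB 'n'
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    spec: CountSimSpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Simulate a two-group count matrix with planted differential genes.

    Returns (matrix, annotation, truth) where ``truth`` lists every planted
    gene with its true log2 fold change (group B over group A).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.samples_per_group
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    label_a, label_b = spec.group_labels
    sample_ids = [f"{label_a}_{j + 1}" for j in range(n)] + [
        f"{label_b}_{j + 1}" for j in range(n)
    ]

    mu = np.full((spec.n_genes, 2 * n), spec.baseline_mean, dtype=float)
    for gi, lfc in spec.planted_degs:
        mu[gi, n:] = spec.baseline_mean * 2.0**lfc

    if spec.library_factor_range is not None:
        lo, hi = spec.library_factor_range
        factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))
    else:
        factors = np.ones(2 * n)
    counts = _nb_draw(rng, mu * factors, spec.dispersion)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "counts"
    )
    annotation = SampleAnnotation.from_groups(
        {sid: (label_a if j < n else label_b) for j, sid in enumerate(sample_ids)}
    )
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[gi] for gi, _ in spec.planted_degs],
            "true_log2_fc": [lfc for _, lfc in spec.planted_degs],
        }
    )
    return matrix, annotation, truth


@dataclass(frozen=True)
class TimecourseSimSpec:
    """Log2 time-course simulation with genes planted into model profiles.

    A gene planted into profile ``p`` has noiseless series equal to
    ``step_size`` times the profile's cumulative-change template, anchored at
    0 for the first time point; unplanted genes are flat plus noise.
    """

    n_genes: int = 500
    time_points: tuple[str, ...] = DEFAULT_TIMEPOINTS
    planted_profiles: tuple[tuple[int, int], ...] = ()  # (gene index, profile id)
    unit_change_bound: int = 1
    step_size: float = 1.0
    noise_sd: float = 0.25
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.time_points) < 2:
            raise SimSpecError("need at least 2 time points")
        if self.noise_sd < 0:
            raise SimSpecError("noise_sd must be non-negative")
        if self.step_size <= 0:
            raise SimSpecError("step_size must be positive")
        if self.replicates < 1:
            raise SimSpecError("replicates must be >= 1")
        n_profiles = (2 * self.unit_change_bound + 1) ** (len(self.time_points) - 1) - 1
        idx = [i for i, _ in self.planted_profiles]
        if len(set(idx)) != len(idx):
            raise SimSpecError("planted gene indices must be unique")
        for gi, pid in self.planted_profiles:
            if gi < 0 or gi >= self.n_genes:
                raise SimSpecError(f"planted gene index {gi} out of range")
            if pid < 0 or pid >= n_profiles:
                raise SimSpecError(
                    f"profile id {pid} outside universe of {n_profiles} profiles"
                )


def simulate_timecourse(
    spec: TimecourseSimSpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Simulate a log2 series matrix; returns (matrix, annotation, truth).

    ``truth`` maps each planted gene to its profile id (unplanted genes get
    profile id −1, i.e. flat).
    """
    rng = np.random.default_rng(spec.seed)
    profiles = enumerate_profiles(len(spec.time_points), spec.unit_change_bound)
    templates = {p.profile_id: np.asarray(p.template, dtype=float) for p in profiles}

    T = len(spec.time_points)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    clean = np.zeros((spec.n_genes, T))
    planted = dict(spec.planted_profiles)
    for gi, pid in planted.items():
        clean[gi] = spec.step_size * templates[pid]

    cols: list[str] = []
    tp_of_col: dict[str, str] = {}
    blocks = []
    for tj, tp in enumerate(spec.time_points):
        for r in range(spec.replicates):
            cols.append(f"{tp}_r{r + 1}" if spec.replicates > 1 else tp)
            tp_of_col[cols[-1]] = tp
            blocks.append(clean[:, tj])
    values = np.column_stack(blocks) + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, T * spec.replicates)
    )

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=cols), "log2"
    )
    annotation = SampleAnnotation.from_timepoints(
        tp_of_col, time_order=spec.time_points
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_profile_id": [planted.get(i, -1) for i in range(spec.n_genes)],
        }
    )
    return matrix, annotation, truth


@dataclass(frozen=True)
class CoexprSimSpec:
    """Single-latent-factor co-expression simulation with one planted module.

    Module member i is generated as ``loading_i * f + noise_sd *
    sqrt(1 - loading_i^2) * eps`` with f and eps standard normal, so at the
    default ``noise_sd = 1`` the expected correlation between two members is
    the product of their loadings. The hub carries ``loading_hub``; all other
    members carry the smaller ``loading_member``. Non-members are independent
    noise.
    """

    n_genes: int = 30
    n_samples: int = 100
    module_members: tuple[int, ...] = tuple(range(12))
    hub_index: int = 0
    loading_hub: float = 0.95
    loading_member: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.module_members)) != len(self.module_members):
            raise SimSpecError("module_members must be unique")
        if any(i < 0 or i >= self.n_genes for i in self.module_members):
            raise SimSpecError("module member index out of range")
        if self.hub_index not in self.module_members:
            raise SimSpecError("hub_index must be a module member")
        for name, loading in (
            ("loading_hub", self.loading_hub),
            ("loading_member", self.loading_member),
        ):
            if not (0 < loading <= 1):
                raise SimSpecError(f"{name} must be in (0, 1]")
        if self.loading_member >= self.loading_hub:
            raise SimSpecError("loading_member must be < loading_hub")
        if self.noise_sd < 0:
            raise SimSpecError("noise_sd must be non-negative")
        if self.n_samples < 3:
            raise SimSpecError("need at least 3 samples")


def simulate_coexpression(
    spec: CoexprSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a co-expression matrix; returns (matrix, truth).

    ``truth`` has one row per gene with ``in_module`` and ``is_hub`` flags.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j + 1:03d}" for j in range(spec.n_samples)]

    factor = rng.normal(size=spec.n_samples)
    values = spec.noise_sd * rng.normal(size=(spec.n_genes, spec.n_samples))
    for gi in spec.module_members:
        loading = spec.loading_hub if gi == spec.hub_index else spec.loading_member
        eps = rng.normal(size=spec.n_samples)
        values[gi] = loading * factor + spec.noise_sd * np.sqrt(1 - loading**2) * eps

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), "log2"
    )
    members = set(spec.module_members)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "in_module": [i in members for i in range(spec.n_genes)],
            "is_hub": [i == spec.hub_index for i in range(spec.n_genes)],
        }
    )
    return matrix, truth
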