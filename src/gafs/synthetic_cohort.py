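"""Synthetic FDG-PET-like cohorts with planted class-discriminative hypometabolism.

Real clinical uptake tables cannot be redistributed, so every downstream stage
of the pipeline is exercised on generated cohorts instead. The generative model
is deliberately simple and fully analyzable:

* every region has a shared positive baseline mean uptake;
* each diagnostic class carries a small "planted" set of regions whose mean is
  reduced by ``effect_size`` noise standard deviations (hypometabolism as a
  downward mean shift);
* residual noise is Gaussian with marginal variance ``noise_sd**2`` and either
  exchangeable between-region correlation ``rho`` or block (lobar-style)
  correlation.

Classes may share planted regions, which emulates the regional overlap between
clinically similar syndromes (e.g. aphasia variants) that makes their
differential diagnosis hard and lowers achievable feature cutting rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_table import FeatureTable, RegionAtlas, aal116_atlas

__all__ = ["CohortSpec", "generate_cohort", "recovery_score"]

#: Class sizes mirroring a realistic specialist-clinic referral mix
#: (dementia syndromes vs a smaller healthy control group).
DEFAULT_CLASS_COUNTS = {"AD": 88, "bvFTD": 81, "PPA": 68, "HC": 39}


@dataclass
class CohortSpec:
    """Recipe for one synthetic diagnostic cohort.

    Parameters
    ----------
    class_counts:
        Subjects per diagnostic label; all counts >= 1.
    n_regions:
        Size of the feature pool (default 116, the AAL atlas).
    planted:
        For each class, the 0-based region indices that are hypometabolic in
        that class. Healthy-control-style classes simply plant nothing.
    effect_size:
        Mean reduction of planted regions, in units of ``noise_sd`` (>= 0).
    baseline_mean:
        Shared normalized-uptake baseline (> 0).
    noise_sd:
        Marginal noise standard deviation per region (> 0).
    correlation:
        Exchangeable between-region correlation rho in [0, 1).
    block_size:
        If set, correlation is applied within contiguous blocks of this many
        regions (a crude lobar structure) instead of exchangeably across all.
    seed:
        Generator seed; identical spec + seed reproduces the table bit for bit.
    """

    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_regions: int = 116
    planted: dict[str, frozenset[int]] = field(default_factory=dict)
    effect_size: float = 1.5
    baseline_mean: float = 1.0
    noise_sd: float = 0.1
    correlation: float = 0.0
    block_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not self.class_counts:
            raise ValueError("at least one class required")
        for lab, count in self.class_counts.items():
            if count < 1:
                raise ValueError(f"class {lab!r} has count {count}; counts must be >= 1")
        for lab, regions in self.planted.items():
            if lab not in self.class_counts:
                raise ValueError(f"planted class {lab!r} not in class_counts")
            if any(not (0 <= r < self.n_regions) for r in regions):
                raise ValueError(f"planted indices for {lab!r} outside [0, {self.n_regions})")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.baseline_mean <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_mean and noise_sd must be > 0")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must be in [0, 1)")
        if self.block_size is not None and self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def _correlated_noise(rng: np.random.Generator, m: int, spec: CohortSpec) -> np.ndarray:
    """m x n_regions Gaussian noise with unit marginal variance and the spec's
    correlation structure, scaled by noise_sd."""
    n = spec.n_regions
    rho = spec.correlation
    indiv = rng.standard_normal((m, n))
    if rho == 0.0:
        z = indiv
    elif spec.block_size is None:
        shared = rng.standard_normal((m, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
    else:
        z = np.sqrt(1.0 - rho) * indiv
        for start in range(0, n, spec.block_size):
            stop = min(start + spec.block_size, n)
            shared = rng.standard_normal((m, 1))
            z[:, start:stop] += np.sqrt(rho) * shared
    return spec.noise_sd * z


def generate_cohort(
    spec: CohortSpec, atlas: RegionAtlas | None = None
) -> tuple[FeatureTable, dict[str, frozenset[int]]]:
    """Draw one cohort; returns the table and the ground-truth planted map.

    Rows are grouped by class in ``class_counts`` insertion order with subject
    ids ``S0001, S0002, ...``. Planted regions of class c have mean
    ``baseline_mean - effect_size * noise_sd``; all other cells have mean
    ``baseline_mean``.
    """
    if atlas is None:
        if spec.n_regions == 116:
            atlas = aal116_atlas()
        else:
            atlas = RegionAtlas(tuple(f"R{i:03d}" for i in range(spec.n_regions)))
    if atlas.size != spec.n_regions:
        raise ValueError(f"atlas has {atlas.size} regions, spec says {spec.n_regions}")

    rng = np.random.default_rng(spec.seed)
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for lab, count in spec.class_counts.items():
        mean = np.full(spec.n_regions, spec.baseline_mean)
        for r in spec.planted.get(lab, frozenset()):
            mean[r] -= spec.effect_size * spec.noise_sd
        blocks.append(mean + _correlated_noise(rng, count, spec))
        labels.extend([lab] * count)
    values = np.vstack(blocks)
    subject_ids = [f"S{i + 1:04d}" for i in range(values.shape[0])]
    ground_truth = {lab: frozenset(spec.planted.get(lab, frozenset())) for lab in spec.class_counts}
    return FeatureTable(subject_ids, labels, values, atlas), ground_truth


def recovery_score(selected: frozenset[int] | set[int], planted: frozenset[int] | set[int]) -> float:
    """Jaccard index between a selected region set and the planted truth.

    1.0 for identical non-empty sets, 0.0 for disjoint sets; two empty sets
    score 0.0 by convention (nothing was there to recover).
    """
    selected, planted = set(selected), set(planted)
    union = selected | planted
    if not union:
        return 0.0
    return len(selected & planted) / len(union)
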