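"""PCA variance-coverage baseline.

The comparison point for the evolutionary selector: how many principal
components of the uptake matrix are needed to cover a stated fraction of the
total variance? Components are directions in region space, not regions, so
the count is a dimensionality figure rather than an interpretable region
subset — which is precisely the contrast the baseline illustrates.

PCA is computed on mean-centered, unscaled columns (covariance PCA), matching
intensity-normalized uptake inputs whose common scale is meaningful; a
correlation-mode switch standardizes columns first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import DegenerateInputError
from .feature_table import FeatureTable

__all__ = ["VarianceCoverage", "components_for_variance"]


@dataclass(frozen=True)
class VarianceCoverage:
    n_components: int
    covered_fraction: float
    threshold: float


def components_for_variance(
    table: FeatureTable, threshold: float, mode: str = "covariance"
) -> VarianceCoverage:
    """Minimal component count whose cumulative explained variance reaches
    ``threshold``.

    Eigenvalues of the (co)variance matrix are taken in descending order; the
    returned count is the smallest c with cumulative fraction >= threshold,
    together with the fraction actually achieved. ``threshold = 1.0`` yields
    the rank of the centered matrix.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if table.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown mode {mode!r}")

    x = table.values.astype(float)
    if mode == "correlation":
        sd = x.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise DegenerateInputError("constant table: zero total variance")
        x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    if np.allclose(x, x[0]):
        raise DegenerateInputError("constant table: zero total variance")

    pca = PCA(n_components=min(table.n_subjects - 1, table.n_regions))
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    # guard against float shortfall at threshold 1.0: compare against the
    # achieved total, which equals 1 up to rounding once all rank directions are in
    reachable = cum >= min(threshold, cum[-1]) - 1e-12
    c = int(np.argmax(reachable)) + 1
    if threshold >= cum[-1]:
        # rank of the centered matrix: components with non-negligible variance
        c = int((ratios > ratios[0] * 1e-12).sum())
    return VarianceCoverage(c, float(cum[c - 1]), threshold)
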