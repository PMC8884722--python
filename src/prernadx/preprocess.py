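"""Low-count filtering and variance-stabilizing normalization.

Features are kept when they reach a minimum read count in a minimum
fraction of samples (defaults: >=5 reads in >=80% of samples).  Library
depth is removed with median-of-ratios size factors, and counts are then
put on a variance-stabilized scale with a shifted log transform,
``log2(count / size_factor + 1)`` — a deliberate, documented surrogate for
the model-fitted spline VST used in differential-expression packages,
chosen because it is closed-form, monotone, and stable on small cohorts.
The normalization is pluggable: any callable with the same signature can
replace :func:`vst_normalize` downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, CohortError


@dataclass
class NormalizedMatrix:
    """Normalized expression values with their size factors and axis labels."""

    values: np.ndarray  # (n_samples, n_features)
    size_factors: np.ndarray  # (n_samples,)
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise CohortError("NormalizedMatrix dimensions inconsistent with labels")
        if self.size_factors.shape != (len(self.sample_ids),):
            raise CohortError("one size factor per sample required")
        if (self.size_factors <= 0).any():
            raise CohortError("size factors must be positive")
        if not np.all(np.isfinite(self.values)):
            raise CohortError("normalized values must be finite")


def filter_low_counts(
    cohort: Cohort, min_reads: int = 5, min_fraction: float = 0.8
) -> Cohort:
    """Keep features with >= ``min_reads`` counts in >= ``min_fraction`` of samples.

    The sample set is unchanged and the order of retained features is
    preserved.  Idempotent.  Removing every feature is valid but warned
    about.
    """
    if min_reads < 0:
        raise CohortError("min_reads must be >= 0")
    if not 0.0 < min_fraction <= 1.0:
        raise CohortError("min_fraction must be in (0, 1]")
    if cohort.n_samples == 0 or cohort.n_features == 0:
        raise CohortError("cannot filter an empty cohort")

    frac_expressed = (cohort.counts >= min_reads).mean(axis=0)
    # use a small tolerance so exact boundaries (e.g. 4/5 >= 0.8) are kept
    keep = frac_expressed >= min_fraction - 1e-12
    kept_ids = [f for f, k in zip(cohort.feature_ids, keep) if k]
    if not kept_ids:
        warnings.warn(
            "low-count filter removed every feature", UserWarning, stacklevel=2
        )
        return Cohort(
            counts=np.zeros((cohort.n_samples, 0), dtype=np.int64),
            samples=list(cohort.samples),
            annotation=[],
        )
    return cohort.subset_features(kept_ids)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    The reference is the per-feature geometric mean over samples,
    restricted to features with nonzero counts in every sample; each
    sample's factor is the median ratio of its counts to that reference.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise CohortError("counts must be a non-empty 2-D matrix")
    all_positive = (counts > 0).all(axis=0)
    if not all_positive.any():
        raise CohortError(
            "no feature has nonzero counts in every sample; "
            "apply filter_low_counts first"
        )
    ref = counts[:, all_positive].astype(float)
    log_geomean = np.log(ref).mean(axis=0)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=1))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def vst_normalize(cohort: Cohort, factors: np.ndarray) -> NormalizedMatrix:
    """Shifted-log normalization: ``log2(count / factor + 1)``.

    Monotone in counts within each sample, zero maps to zero, and the
    size factors flatten library-depth differences before the log.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (cohort.n_samples,):
        raise CohortError("need exactly one size factor per sample")
    if (factors <= 0).any():
        raise CohortError("size factors must be positive")
    values = np.log2(cohort.counts / factors[:, None] + 1.0)
    return NormalizedMatrix(
        values=values,
        size_factors=factors,
        sample_ids=cohort.sample_ids,
        feature_ids=cohort.feature_ids,
    )


def preprocess(
    cohort: Cohort, min_reads: int = 5, min_fraction: float = 0.8
) -> tuple[Cohort, NormalizedMatrix]:
    """Filter, estimate size factors, and normalize in one call."""
    filtered = filter_low_counts(cohort, min_reads=min_reads, min_fraction=min_fraction)
    factors = size_factors(filtered.counts)
    return filtered, vst_normalize(filtered, factors)
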