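"""Abundance-based diversity: Hill numbers, rarefaction, sample coverage.

Following the individual/species mapping for repertoires, one unique cDNA
molecule is one "individual" and one clonotype is one "species". The Hill
number of order q is the effective number of equally abundant clonotypes;
q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the inverse
Simpson concentration. Rarefaction is by Monte-Carlo subsampling without
replacement (multivariate hypergeometric), reporting the mean and Monte-
Carlo standard error at each subsample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import UndefinedDiversityError


def _clean(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("abundance vector must be 1-D")
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedDiversityError("diversity undefined for an empty sample")
    return x


def hill_diversity(counts, q: float = 1.0) -> float:
    """Hill number of order q: (sum p_i^q)^(1/(1-q)), exp-entropy at q=1.

    Continuous at q=1 (orders within 1e-9 of 1 use the entropy limit).
    Scale-invariant: depends on proportions only.
    """
    if q < 0:
        raise ValueError("Hill order q must be nonnegative")
    x = _clean(counts)
    p = x / x.sum()
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def sample_coverage(counts) -> float:
    """Good–Turing sample completeness with the bias-corrected form.

    C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)], where f1 and f2 are
    the numbers of singleton and doubleton clonotypes. Returns 1 when there
    are no singletons; degrades to 1 - f1/n when the correction denominator
    vanishes (f2 = 0 edge cases).
    """
    x = _clean(counts)
    n = x.sum()
    f1 = float(np.sum(x == 1))
    f2 = float(np.sum(x == 2))
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        return float(1.0 - f1 / n)
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def rarefied_diversity(
    counts,
    m: int,
    reps: int = 100,
    seed: Optional[int] = None,
    q: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Mean and MC standard error of Hill diversity at subsample size m.

    Draws ``reps`` subsamples of exactly m molecules without replacement
    and evaluates the order-q Hill number on each. Deterministic given a
    seed. Subsampling beyond the observed depth is not supported.
    """
    x = np.asarray(counts)
    total = int(x.sum())
    if m <= 0:
        raise ValueError("subsample size m must be positive")
    if m > total:
        raise ValueError(f"subsample size m={m} exceeds sample depth n={total}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if m == total:
        # a full draw without replacement recovers the sample exactly
        return hill_diversity(x, q=q), 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    whole = x[x > 0].astype(np.int64)
    values = np.empty(reps)
    for i in range(reps):
        sub = rng.multivariate_hypergeometric(whole, m)
        values[i] = hill_diversity(sub, q=q)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, se


@dataclass
class DiversityResult:
    """Observed diversity plus rarefaction curve and coverage for a sample."""

    q: float
    d_obs: float
    curve: list[tuple[int, float, float]]
    coverage: float
    reps: int
    seed: Optional[int]


def rarefaction_curve(
    counts,
    grid: Sequence[int],
    reps: int = 100,
    seed: Optional[int] = None,
    q: float = 1.0,
) -> DiversityResult:
    """Rarefaction curve over a sorted grid of subsample sizes.

    The final point at m = n equals the observed diversity exactly (a full
    draw without replacement recovers the sample).
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    total = int(np.asarray(counts).sum())
    for m in grid:
        if m > total:
            raise ValueError(f"grid point m={m} exceeds sample depth n={total}")
    rng = np.random.default_rng(seed)
    curve = []
    for m in grid:
        mean, se = rarefied_diversity(counts, m, reps=reps, q=q, rng=rng)
        curve.append((int(m), mean, se))
    return DiversityResult(
        q=q,
        d_obs=hill_diversity(counts, q=q),
        curve=curve,
        coverage=sample_coverage(counts),
        reps=reps,
        seed=seed,
    )


def auto_grid(n: int, k: int = 8) -> list[int]:
    """k log-spaced subsample sizes from 1 to n (deduplicated, ends at n)."""
    if n < 1:
        raise ValueError("sample depth must be >= 1")
    pts = np.unique(np.round(np.geomspace(1, n, num=k)).astype(int))
    return [int(p) for p in pts]


def relative_diversity(
    values: Mapping[str, float], reference_ids: Sequence[str]
) -> dict[str, float]:
    """Per-sample diversity divided by the mean over reference samples."""
    if not reference_ids:
        raise ValueError("reference set must be nonempty")
    ref = [values[r] for r in reference_ids]
    mean = float(np.mean(ref))
    if mean == 0:
        raise ValueError("reference mean diversity is zero")
    return {k: float(v) / mean for k, v in values.items()}
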