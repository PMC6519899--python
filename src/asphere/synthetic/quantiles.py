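"""Five-number-summary distributions.

Published cohort results often report only median, interquartile range and
range per group. The distribution model used throughout this package is the
piecewise-linear quantile function through those five points at
probabilities (0, .25, .5, .75, 1): it reproduces every printed summary
statistic exactly in the large-sample limit while assuming nothing else.
Sampling is inverse-transform; the implied density is piecewise uniform
with mass 1/4 on each inter-quantile interval (a zero-width interval is a
point mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_PROBS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


@dataclass(frozen=True)
class FiveNumberSummary:
    """minimum <= q1 <= median <= q3 <= maximum (ASP in %, or diameter in mm)."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        pts = self.points
        if np.any(np.diff(pts) < 0):
            raise ValueError(f"five-number summary must be non-decreasing, got {tuple(pts)}")

    @property
    def points(self) -> np.ndarray:
        return np.array([self.minimum, self.q1, self.median, self.q3, self.maximum], float)

    def quantile(self, u) -> np.ndarray:
        """Piecewise-linear quantile function through the five points."""
        return np.interp(np.asarray(u, float), _PROBS, self.points)

    def cdf(self, x: float) -> float:
        """Left-continuous inverse of :meth:`quantile` (flat pieces -> jumps)."""
        pts = self.points
        if x <= pts[0]:
            return 0.0
        if x >= pts[-1]:
            return 1.0
        # np.interp on the swapped axes picks a valid probability on flats
        return float(np.interp(x, pts, _PROBS))


def sample_from_summary(
    summary: FiveNumberSummary, n: int, rng: np.random.Generator, lower_bound: float | None = None
) -> np.ndarray:
    """Inverse-transform sample of size ``n``; deterministic given ``rng``.

    ``lower_bound`` truncates the distribution from below (used to keep
    generated lesion diameters above an eligibility threshold) by sampling
    the uniform variate from [cdf(lower_bound), 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = 0.0
    if lower_bound is not None:
        if lower_bound > summary.maximum:
            raise ValueError(
                f"lower bound {lower_bound} exceeds distribution maximum {summary.maximum}"
            )
        lo = summary.cdf(lower_bound)
    u = rng.uniform(lo, 1.0, size=int(n))
    x = summary.quantile(u)
    if lower_bound is not None:
        x = np.maximum(x, lower_bound)
    return x


def _uniform_exceeds(c: float, d: float, a: float, b: float) -> float:
    """P(U > V) + 0.5 P(U = V) for U~Unif[c,d], V~Unif[a,b] (either may be a point)."""
    if c == d and a == b:
        return 1.0 if c > a else (0.5 if c == a else 0.0)
    if c == d:  # U degenerate, V continuous
        return (min(max(c, a), b) - a) / (b - a)
    if a == b:  # V degenerate, U continuous
        return (d - min(max(a, c), d)) / (d - c)
    # integrate F_V(u) over [c, d]
    total = 0.0
    for s, e in _segments(c, d, a, b):
        if e <= a:
            continue
        if s >= b:
            total += (b - a) * (e - s)
        else:
            total += ((e - a) ** 2 - (s - a) ** 2) / 2.0
    return total / ((d - c) * (b - a))


def _segments(c, d, a, b):
    cuts = sorted({c, d, min(max(a, c), d), min(max(b, c), d)})
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1) if cuts[i + 1] > cuts[i]]


def quantile_model_auc(negative: FiveNumberSummary, positive: FiveNumberSummary) -> float:
    """Exact P(X+ > X-) + 0.5 P(X+ = X-) under the piecewise-linear quantile model.

    This is the model-implied ROC AUC for scores drawn from the two
    summaries, computed by closed-form integration over the 4x4 grid of
    piecewise-uniform components (weight 1/16 each).
    """
    npts, ppts = negative.points, positive.points
    auc = 0.0
    for i in range(4):
        for j in range(4):
            auc += _uniform_exceeds(ppts[j], ppts[j + 1], npts[i], npts[i + 1])
    return auc / 16.0
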