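"""Statistical comparison machinery for SCORE metric distributions.

Metric samples from eggshell sections are right-skewed and of unequal
length across eggs, which shapes every choice here: normality is screened
(never silently switched on) with Shapiro-Wilk; outliers are removed with
an asymmetric IQR rule whose upper multiplier exceeds the lower; location
differences get percentile bootstrap CIs; distributions are compared with
the exact two-sample Kolmogorov-Smirnov test; and the three per-metric
p-values of an egg pair — which are not independent, all being functions of
the same surface — are combined with the harmonic mean rather than Fisher's
method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import ParameterError

__all__ = [
    "OutlierPolicy",
    "BootstrapResult",
    "KSResult",
    "PairwiseMatrix",
    "shapiro_wilk",
    "iqr_filter",
    "bootstrap_mean_diff",
    "ks_exact",
    "spearman",
    "harmonic_mean_p",
    "pairwise_compare",
]

EXACT_KS_GUARD = 10_000  # largest n*m for which the exact null is computed

METRICS = ("complexity", "relief", "orientation")


@dataclass(frozen=True)
class OutlierPolicy:
    """Asymmetric IQR fence: a larger multiplier on the upper bound keeps
    the right tail of skewed metric distributions from being over-trimmed
    symmetric-style while still catching genuine spikes."""

    lower_multiplier: float = 1.5
    upper_multiplier: float = 3.0
    quartile_method: str = "linear"

    def __post_init__(self):
        if not self.lower_multiplier > 0:
            raise ParameterError("lower_multiplier must be positive")
        if self.upper_multiplier < self.lower_multiplier:
            raise ParameterError("upper_multiplier must be >= lower_multiplier")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    lower: float
    upper: float
    iterations: int
    seed: int


class KSResult(tuple):
    """(D, p) tuple that also records which null computation was used."""

    def __new__(cls, statistic, pvalue, method):
        self = super().__new__(cls, (statistic, pvalue))
        self.statistic = statistic
        self.pvalue = pvalue
        self.method = method
        return self


@dataclass
class PairwiseMatrix:
    """Per-metric and harmonic-mean-combined p-value matrices over eggs."""

    labels: list
    per_metric: dict = field(default_factory=dict)  # metric -> DataFrame
    combined: pd.DataFrame | None = None
    alpha: float = 0.05

    @property
    def n_pairs(self) -> int:
        return len(self.labels) * (len(self.labels) - 1) // 2

    def significant_fraction(self, labels_a=None, labels_b=None) -> float:
        """Fraction of pairs with combined p < alpha, optionally restricted
        to pairs straddling two label groups."""
        pairs = self._select_pairs(labels_a, labels_b)
        if not pairs:
            return float("nan")
        hits = sum(1 for a, b in pairs if self.combined.loc[a, b] < self.alpha)
        return hits / len(pairs)

    def _select_pairs(self, labels_a, labels_b):
        if labels_a is None:
            return list(combinations(self.labels, 2))
        set_a, set_b = set(labels_a), set(labels_b)
        return [
            (a, b)
            for a, b in combinations(self.labels, 2)
            if (a in set_a and b in set_b) or (a in set_b and b in set_a)
        ]


# ---------------------------------------------------------------------------


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test; a screening report, never a switch."""
    x = np.asarray(sample, dtype=np.float64)
    if not 3 <= len(x) <= 5000:
        raise ParameterError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ParameterError("sample has zero variance")
    res = _sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def iqr_filter(sample, policy: OutlierPolicy = OutlierPolicy()):
    """Single-pass asymmetric IQR outlier removal.

    Removes x < Q1 - lower*IQR and x > Q3 + upper*IQR with quartiles by
    linear interpolation between order statistics; input order of the
    retained values is preserved.
    """
    x = np.asarray(sample, dtype=np.float64)
    if len(x) < 4:
        raise ParameterError(f"IQR filtering needs n >= 4, got n={len(x)}")
    q1, q3 = np.percentile(x, [25, 75], method=policy.quartile_method)
    iqr = q3 - q1
    lo = q1 - policy.lower_multiplier * iqr
    hi = q3 + policy.upper_multiplier * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


def bootstrap_mean_diff(a, b, iterations: int = 1000, seed: int = 0) -> BootstrapResult:
    """Percentile 95% CI of mean(a) - mean(b) by resampling both samples
    with replacement each iteration; fully reproducible given the seed."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("bootstrap samples must be non-empty")
    if iterations < 100:
        raise ParameterError("use at least 100 bootstrap iterations")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(iterations, len(a)))
    ib = rng.integers(0, len(b), size=(iterations, len(b)))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lower, upper = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(a.mean() - b.mean()),
        lower=float(lower),
        upper=float(upper),
        iterations=iterations,
        seed=seed,
    )


def ks_exact(a, b) -> KSResult:
    """Exact two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two ECDFs; the p-value is the
    exact permutation null probability P(D' >= D) (network/recursion
    algorithm) whenever n*m <= 10,000, falling back to the asymptotic
    distribution above that guard (recorded in ``result.method``).  Samples
    may have different lengths.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("KS samples must be non-empty")
    method = "exact" if len(a) * len(b) <= EXACT_KS_GUARD else "asymp"
    with warnings.catch_warnings():
        # ties make the exact null conservative; same behavior as R's ks.test
        warnings.simplefilter("ignore")
        res = _sps.ks_2samp(a, b, method=method)
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def spearman(x, y) -> float:
    """Spearman's rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ParameterError("samples must have equal length")
    if len(x) < 3:
        raise ParameterError("Spearman correlation needs n >= 3")
    return float(_sps.spearmanr(x, y).statistic)


def harmonic_mean_p(pvalues, calibrated: bool = False) -> float:
    """Combine p-values with the (unweighted) harmonic mean k / sum(1/p).

    The plain harmonic mean is the default combination for the three
    non-independent metric tests.  ``calibrated=True`` instead returns the
    asymptotically exact tail probability of the harmonic mean under the
    null (the reciprocal follows a Landau distribution with location
    ln(k) + 0.874 and scale pi/2).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ParameterError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    hmp = len(p) / np.sum(1.0 / p)
    if not calibrated:
        return float(hmp)
    k = len(p)
    if k == 1:
        return float(p[0])
    loc = math.log(k) + 0.874367040387922
    return float(min(1.0, _sps.landau.sf(1.0 / hmp, loc=loc, scale=math.pi / 2)))


# ---------------------------------------------------------------------------


def pairwise_compare(
    records,
    alpha: float = 0.05,
    policy: OutlierPolicy = OutlierPolicy(),
    prefiltered: bool = False,
    calibrated: bool = False,
) -> PairwiseMatrix:
    """All-pairs egg comparison: per-metric exact KS p-values and their
    harmonic-mean combination.

    ``records`` is an iterable of :class:`~eggscore.metrics.ScoreRecord`;
    outlier filtering is applied per egg per metric (unless
    ``prefiltered``).  Eggs with fewer than 2 retained sections are excluded
    with a warning.  Matrices are symmetric with a unit diagonal.
    """
    by_egg: dict[str, dict[str, list[float]]] = {}
    for r in records:
        egg = by_egg.setdefault(r.egg_id, {m: [] for m in METRICS})
        for m in METRICS:
            egg[m].append(getattr(r, m))

    samples: dict[str, dict[str, np.ndarray]] = {}
    for egg_id, metrics_map in by_egg.items():
        filtered = {}
        ok = True
        for m in METRICS:
            x = np.asarray(metrics_map[m], dtype=np.float64)
            if not prefiltered and len(x) >= 4:
                x, _ = iqr_filter(x, policy)
            if len(x) < 2:
                ok = False
            filtered[m] = x
        if ok:
            samples[egg_id] = filtered
        else:
            warnings.warn(
                f"egg {egg_id!r} has fewer than 2 retained sections; excluded",
                stacklevel=2,
            )
    labels = sorted(samples)
    if len(labels) < 2:
        raise ParameterError("need at least 2 eggs with retained sections")

    per_metric = {
        m: pd.DataFrame(1.0, index=labels, columns=labels) for m in METRICS
    }
    combined = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        ps = []
        for m in METRICS:
            p = ks_exact(samples[a][m], samples[b][m]).pvalue
            per_metric[m].loc[a, b] = per_metric[m].loc[b, a] = p
            ps.append(p)
        h = harmonic_mean_p(ps, calibrated=calibrated)
        combined.loc[a, b] = combined.loc[b, a] = h
    return PairwiseMatrix(
        labels=labels, per_metric=per_metric, combined=combined, alpha=alpha
    )
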