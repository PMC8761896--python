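"""Two-sample comparison of antibody-variant feature distributions.

The comparison machinery is a two-sample Kolmogorov-Smirnov test per feature
with Bonferroni control across the features of one comparison call.  Note that
Bonferroni controls the family-wise error rate (FWER), not the false-discovery
rate; an optional Benjamini-Hochberg mode is provided for users who want
literal FDR control.

Ties are handled with right-continuous empirical CDFs: ``D`` is the largest
absolute ECDF difference evaluated at the pooled sample points.  The exact
p-value enumerates every way of labelling the pooled multiset (all
``C(n+m, n)`` assignments) and counts those reaching the observed ``D``; it is
used automatically when the enumeration is small enough, otherwise the
classical asymptotic Kolmogorov tail is applied.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb, kolmogorov

from .errors import InsufficientDataError

EXACT_ENUMERATION_BOUND = 100_000


def _ecdf_sup_distance(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| with right-continuous ECDFs."""
    pooled = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


@dataclasses.dataclass(frozen=True)
class KsResult:
    """Two-sample KS statistic and p-value."""

    D: float
    p: float
    n: int
    m: int
    mode: str  # "exact" | "asymptotic"


def _exact_pvalue(pooled: np.ndarray, n: int, d_obs: float) -> float:
    """Permutation-exact p by enumerating all label assignments.

    For each way of choosing which ``n`` of the pooled (sorted) values belong
    to sample x, D is evaluated at the value boundaries; ties in the pooled
    values are handled by only reading the ECDF difference where the next
    value differs (right-continuity).
    """
    N = len(pooled)
    m = N - n
    # boundaries where the ECDF difference is observable
    observable = np.append(pooled[:-1] != pooled[1:], True)
    count = 0
    total = 0
    labels = np.zeros(N, dtype=bool)
    for combo in itertools.combinations(range(N), n):
        labels[:] = False
        labels[list(combo)] = True
        cx = np.cumsum(labels) / n
        cy = np.cumsum(~labels) / m
        d = np.max(np.abs(cx - cy)[observable])
        count += d >= d_obs - 1e-12
        total += 1
    return count / total


def _asymptotic_pvalue(d: float, n: int, m: int) -> float:
    """Classical Kolmogorov tail at ``sqrt(nm/(n+m)) * D``."""
    return float(kolmogorov(math.sqrt(n * m / (n + m)) * d))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    exact_bound: int = EXACT_ENUMERATION_BOUND,
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    Exact enumeration is used when ``C(n+m, n) <= exact_bound``; otherwise
    the asymptotic Kolmogorov distribution (with small-sample correction).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("both samples need at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    n, m = len(x), len(y)
    d = _ecdf_sup_distance(x, y)
    if comb(n + m, n, exact=True) <= exact_bound:
        pooled = np.sort(np.concatenate([x, y]))
        return KsResult(D=d, p=_exact_pvalue(pooled, n, d), n=n, m=m, mode="exact")
    return KsResult(D=d, p=_asymptotic_pvalue(d, n, m), n=n, m=m, mode="asymptotic")


# --- multiple-testing control -----------------------------------------------


@dataclasses.dataclass
class CorrectionResult:
    flags: list[bool]
    adjusted_p: list[float]
    threshold: float | None  # per-test threshold (Bonferroni only)
    method: str
    alpha: float
    m: int


def bonferroni(pvalues: Sequence[float], alpha: float = 0.01, m: int | None = None) -> CorrectionResult:
    """Bonferroni correction: flag tests with ``p < alpha / m``.

    ``m`` defaults to the number of p-values; adjusted p-values
    ``min(1, m * p)`` are reported alongside.
    """
    p = list(map(float, pvalues))
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = m if m is not None else len(p)
    if m_eff < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m_eff
    return CorrectionResult(
        flags=[v < threshold for v in p],
        adjusted_p=[min(1.0, m_eff * v) for v in p],
        threshold=threshold,
        method="bonferroni",
        alpha=alpha,
        m=m_eff,
    )


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.01) -> CorrectionResult:
    """Benjamini-Hochberg FDR control (for users who want literal FDR)."""
    from statsmodels.stats.multitest import multipletests

    p = list(map(float, pvalues))
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return CorrectionResult(
        flags=list(map(bool, reject)),
        adjusted_p=list(map(float, adjusted)),
        threshold=None,
        method="benjamini-hochberg",
        alpha=alpha,
        m=len(p),
    )


# --- variant comparison ------------------------------------------------------


@dataclasses.dataclass
class FeatureComparison:
    feature: str
    ks: KsResult
    significant: bool
    stars: str          # "**", "*", or "ns"
    median_difference: float


@dataclasses.dataclass
class ComparisonReport:
    """Per-feature KS results with multiple-testing control for one pair."""

    features: list[FeatureComparison]
    alpha: float
    m: int
    method: str
    threshold: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": f.feature,
                "D": f.ks.D,
                "p": f.ks.p,
                "p_adjusted": min(1.0, self.m * f.ks.p) if self.method == "bonferroni" else None,
                "mode": f.ks.mode,
                "median_difference": f.median_difference,
                "significant": f.significant,
                "stars": f.stars,
            }
            for f in self.features
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "m": self.m,
            "method": self.method,
            "threshold": self.threshold,
            "features": [
                {
                    "feature": f.feature,
                    "D": f.ks.D,
                    "p": f.ks.p,
                    "n": f.ks.n,
                    "m": f.ks.m,
                    "mode": f.ks.mode,
                    "median_difference": f.median_difference,
                    "significant": f.significant,
                    "stars": f.stars,
                }
                for f in self.features
            ],
        }


def _values(series) -> np.ndarray:
    return np.asarray(getattr(series, "values", series), float)


def compare_variants(
    a: Mapping[str, object],
    b: Mapping[str, object],
    alpha: float = 0.01,
    m: int | None = None,
    correction: str = "bonferroni",
) -> ComparisonReport:
    """Compare two variants feature-by-feature.

    ``a`` and ``b`` map feature names to series (FeatureSeries or arrays);
    the feature-name sets must match.  Star coding follows the usual figure
    legend convention: ``**`` for corrected significance at ``alpha``, ``*``
    for uncorrected p < 0.05, ``ns`` otherwise.  The correction scope is the
    features of this call unless ``m`` overrides it.
    """
    if set(a) != set(b):
        raise ValueError(
            f"feature names differ: {sorted(set(a) ^ set(b))}"
        )
    names = sorted(a)
    ks_results = {name: ks_two_sample(_values(a[name]), _values(b[name])) for name in names}
    pvalues = [ks_results[name].p for name in names]
    if correction == "bonferroni":
        corr = bonferroni(pvalues, alpha=alpha, m=m)
    elif correction in ("bh", "benjamini-hochberg"):
        corr = benjamini_hochberg(pvalues, alpha=alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    features = []
    for name, flag in zip(names, corr.flags):
        ks = ks_results[name]
        stars = "**" if flag else ("*" if ks.p < 0.05 else "ns")
        features.append(
            FeatureComparison(
                feature=name,
                ks=ks,
                significant=flag,
                stars=stars,
                median_difference=float(np.median(_values(b[name])) - np.median(_values(a[name]))),
            )
        )
    return ComparisonReport(
        features=features,
        alpha=alpha,
        m=corr.m,
        method=corr.method,
        threshold=corr.threshold,
    )
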