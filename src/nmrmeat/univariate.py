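"""Per-bucket Kruskal-Wallis screening with Šidák-corrected significance.

The Kruskal-Wallis test is the rank-based (non-parametric) analogue of a
one-way ANOVA: pooled observations are midranked, and

    H = 12 / (n (n+1)) * sum_i n_i (Rbar_i - (n+1)/2)^2,

corrected for ties by dividing by 1 - sum(t^3 - t) / (n^3 - n), is referred
to the chi-square distribution with g-1 degrees of freedom.  Scanning every
retained bucket repeats the test k times, so the family-wise significance
level alpha is Šidák-corrected to the per-test level 1 - (1-alpha)^(1/k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .preprocess import FeatureMatrix


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """H statistic and chi-square p-value across >= 2 groups.

    Uses midranks with tie correction.  All observations identical is the
    fully tied degenerate case: H = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    pooled = np.concatenate(arrs)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = rankdata(pooled)
    H = 0.0
    start = 0
    for a in arrs:
        r = ranks[start : start + a.size]
        H += a.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += a.size
    H *= 12.0 / (n * (n + 1))
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    H /= correction
    p = float(chi2.sf(H, df=len(arrs) - 1))
    return float(H), p


def sidak_correct(alpha: float, k: int) -> float:
    """Per-test level 1 - (1 - alpha)^(1/k) controlling family-wise error."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


@dataclass
class KWScanResult:
    """Per-bucket screening outcome across the class groups."""

    bucket_centers: np.ndarray
    H: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # p < alpha_sid
    alpha: float
    alpha_sid: float
    k: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bucket_center": self.bucket_centers,
                "H": self.H,
                "p": self.p,
                "significant": self.significant,
            }
        )

    def significant_centers(self) -> np.ndarray:
        return self.bucket_centers[self.significant]


def scan_buckets(
    fm: FeatureMatrix,
    labels: Sequence[str] | None = None,
    alpha: float = 0.001,
) -> KWScanResult:
    """Kruskal-Wallis per retained bucket, Šidák-corrected over k = bucket count."""
    y = fm.labels if labels is None else np.asarray(labels, dtype=object)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("screening requires at least 2 classes")
    masks = [y == c for c in classes]
    k = fm.n_buckets
    a_sid = sidak_correct(alpha, k)
    H = np.empty(k)
    p = np.empty(k)
    for j in range(k):
        col = fm.values[:, j]
        H[j], p[j] = kruskal_wallis([col[m] for m in masks])
    return KWScanResult(
        bucket_centers=fm.bucket_centers.copy(),
        H=H,
        p=p,
        significant=p < a_sid,
        alpha=alpha,
        alpha_sid=a_sid,
        k=k,
    )


def group_profiles(
    fm: FeatureMatrix,
    labels: Sequence[str] | None = None,
    band: str = "sd",
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> Mapping[str, pd.DataFrame]:
    """Per-class mean bucket profile with a variability band.

    ``band="sd"`` gives mean +/- 1 standard deviation; ``band="percentile"``
    gives the given percentile range.  Returns one DataFrame per class with
    columns mean/lower/upper indexed by bucket center.
    """
    y = fm.labels if labels is None else np.asarray(labels, dtype=object)
    if band not in ("sd", "percentile"):
        raise ValueError("band must be 'sd' or 'percentile'")
    out = {}
    for c in sorted(set(y)):
        V = fm.values[y == c]
        if V.shape[0] == 0:
            raise ValueError(f"class {c!r} is empty")
        mean = V.mean(axis=0)
        if band == "sd":
            sd = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros_like(mean)
            lower, upper = mean - sd, mean + sd
        else:
            lower = np.percentile(V, percentiles[0], axis=0)
            upper = np.percentile(V, percentiles[1], axis=0)
        out[c] = pd.DataFrame(
            {"mean": mean, "lower": lower, "upper": upper},
            index=pd.Index(fm.bucket_centers, name="bucket_center"),
        )
    return out
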