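"""Phenotypic diversity profiling.

Shannon-Weaver diversity indices (natural log), coefficients of variation,
descriptive statistics and trait-trait correlations for germplasm trait
tables. Quantitative traits are discretized into ten classes on a
mean +/- k*sd grid before the index is computed, the convention of the
germplasm-diversity literature; qualitative (graded or categorical) traits
use their observed class frequencies directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TraitMatrix

__all__ = [
    "shannon_weaver",
    "bin_quantitative",
    "trait_summaries",
    "correlate",
    "TraitSummary",
    "CorrelationMatrix",
]


def shannon_weaver(class_frequencies: np.ndarray) -> float:
    """Shannon-Weaver diversity H' = -sum(p ln p), in nats.

    Frequencies must be nonnegative and sum to 1 within 1e-9 (renormalized
    within that tolerance); empty classes contribute 0 (0*ln 0 := 0).
    """
    p = np.asarray(class_frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("negative class frequency")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {total}, not 1")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bin_quantitative(values: np.ndarray, n_classes: int = 10) -> np.ndarray:
    """Class frequencies of a quantitative trait on a mean +/- k*sd grid.

    The interior boundaries sit at mean + k*sd for k = -2, -1.5, ..., +2
    (first class open below, last open above), giving ``n_classes`` = 10
    classes. Missing values are dropped; frequencies sum to 1 over the
    non-missing sample. A constant trait (sd = 0) is rejected.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct non-missing values (sd > 0)")
    m, s = x.mean(), x.std(ddof=1)
    ks = np.linspace(-2, 2, n_classes - 1)
    edges = np.concatenate(([-np.inf], m + ks * s, [np.inf]))
    counts, _ = np.histogram(x, bins=edges)
    return counts / counts.sum()


@dataclass
class TraitSummary:
    """Descriptive statistics and diversity index of one trait."""

    trait: str
    kind: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    cv_percent: float  # 100 * sd / mean
    diversity_index: float  # H', nats


@dataclass
class CorrelationMatrix:
    trait_names: list[str]
    r: np.ndarray  # NaN where undefined (< 3 complete pairs)
    p: np.ndarray

    def get(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.trait_names.index(a), self.trait_names.index(b)
        return float(self.r[i, j]), float(self.p[i, j])

    def stars(self, a: str, b: str) -> str:
        """Significance marker: '**' for p<0.01, '*' for p<0.05, else ''."""
        _, p = self.get(a, b)
        if np.isnan(p):
            return ""
        return "**" if p < 0.01 else "*" if p < 0.05 else ""


def _class_frequencies(codes: np.ndarray) -> np.ndarray:
    codes = codes[~np.isnan(codes)].astype(int)
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    return counts / counts.sum()


def trait_summaries(traits: TraitMatrix) -> list[TraitSummary]:
    """Per-trait mean/sd/min/max, CV% and Shannon-Weaver H'.

    Quantitative traits are binned via :func:`bin_quantitative` for H';
    qualitative traits use their class frequencies directly. An all-missing
    trait is an error naming the trait.
    """
    out: list[TraitSummary] = []
    for j, name in enumerate(traits.trait_names):
        col = traits.values[:, j]
        x = col[~np.isnan(col)]
        if x.size == 0:
            raise ValueError(f"trait {name!r} has no non-missing values")
        kind = traits.kinds[j]
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        if kind == "quantitative":
            h = shannon_weaver(bin_quantitative(x)) if np.unique(x).size > 1 else 0.0
        else:
            h = shannon_weaver(_class_frequencies(x))
        out.append(
            TraitSummary(name, kind, x.size, mean, sd, float(x.min()), float(x.max()), cv, h)
        )
    return out


def correlate(traits: TraitMatrix, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise-complete trait correlations with two-sided p-values.

    Graded qualitative traits enter as their integer class codes. Pairs with
    fewer than 3 complete observations are flagged undefined (NaN).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    X = traits.values
    t = len(traits.trait_names)
    r = np.full((t, t), np.nan)
    p = np.full((t, t), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(t):
        for j in range(i + 1, t):
            mask = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if mask.sum() < 3:
                continue
            xi, xj = X[mask, i], X[mask, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            if method == "pearson":
                res = stats.pearsonr(xi, xj)
            else:
                res = stats.spearmanr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(list(traits.trait_names), r, p)
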