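"""Model-based population structure via the admixture likelihood.

Each individual i carries ancestry fractions q_i over K source populations
and each source k carries an allele-A frequency p_kl at biallelic locus l.
With dosage coding g_il in {0, 1, 2} (count of A alleles; missing loci are
skipped) the log-likelihood is

    L = sum_il [ g_il ln(sum_k q_ik p_kl) + (2 - g_il) ln(sum_k q_ik (1 - p_kl)) ]

maximized by EM from a seeded random start — the maximum-likelihood point
estimate of the same generative model that Bayesian structure software
samples. Replicate runs across a K range feed the Evanno delta-K second
difference statistic for choosing K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import GenotypeMatrix

__all__ = [
    "AdmixtureFit",
    "DeltaKTable",
    "em_admixture",
    "evanno_delta_k",
    "run_structure_scan",
    "match_columns",
]

P_EPS = 1e-6


@dataclass
class AdmixtureFit:
    k: int
    q: np.ndarray  # accession x K ancestry fractions, rows sum to 1
    p: np.ndarray  # locus x K allele-A frequencies in [eps, 1-eps]
    log_likelihood: float
    n_iter: int
    seed: int
    loglik_path: list[float] = field(default_factory=list)

    def assignments(self) -> np.ndarray:
        """Hard group assignment: argmax over the Q row."""
        return self.q.argmax(axis=1)


@dataclass
class DeltaKTable:
    ks: list[int]
    mean_loglik: dict[int, float]
    sd_loglik: dict[int, float]
    delta_k: dict[int, float]  # NaN where undefined

    def best_k(self) -> int:
        defined = {k: v for k, v in self.delta_k.items() if np.isfinite(v)}
        if not defined:
            raise ValueError("delta-K undefined at every K")
        return max(defined, key=lambda k: defined[k])


def _loglik(g: np.ndarray, mask: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    fa = q @ p.T  # (N, L) mixture allele-A frequency
    fb = 1.0 - fa
    with np.errstate(invalid="ignore"):
        ll = g * np.log(fa) + (2.0 - g) * np.log(fb)
    return float(ll[mask].sum())


def em_admixture(
    genotypes: GenotypeMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    Accepts a GenotypeMatrix or a dosage matrix (NaN = missing). Q rows are
    Dirichlet-initialized from ``seed``; P columns start at perturbed
    pooled frequencies. Iterates until the log-likelihood gain drops below
    ``tol`` or ``max_iter`` is hit; P is clamped to [1e-6, 1 - 1e-6]. The
    log-likelihood is non-decreasing across iterations (EM guarantee,
    asserted in the test-suite). All-missing loci are dropped with a
    warning; K may not exceed the number of accessions.
    """
    if isinstance(genotypes, GenotypeMatrix):
        g = genotypes.dosage()
    else:
        g = np.asarray(genotypes, dtype=float)
    n, l = g.shape
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError(f"K={k} exceeds {n} accessions")
    keep = ~np.all(np.isnan(g), axis=0)
    if not keep.all():
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} all-missing locus/loci")
        g = g[:, keep]
        l = g.shape[1]
    mask = ~np.isnan(g)
    g0 = np.where(mask, g, 0.0)

    rng = np.random.default_rng(seed)
    pooled = np.array([g0[mask[:, j], j].mean() / 2.0 if mask[:, j].any() else 0.5
                       for j in range(l)])
    p = np.clip(
        pooled[:, None] + rng.uniform(-0.1, 0.1, size=(l, k)), P_EPS, 1 - P_EPS
    )
    q = rng.dirichlet(np.ones(k), size=n)

    if k == 1:
        q = np.ones((n, 1))
        p = np.clip(pooled[:, None], P_EPS, 1 - P_EPS)
        ll = _loglik(g0, mask, q, p)
        return AdmixtureFit(1, q, p, ll, 0, seed, [ll])

    path: list[float] = []
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        fa = q @ p.T  # (N, L)
        fb = 1.0 - fa
        # responsibilities: expected allele counts attributed to source k
        # a_ilk = g_il * q_ik p_kl / fa_il ; b_ilk analogous with 1-p
        ga = np.where(mask, g0 / fa, 0.0)  # (N, L)
        gb = np.where(mask, (2.0 - g0) / fb, 0.0)
        # sums over loci for q-update: (N, K)
        a_sum = q * (ga @ p)
        b_sum = q * (gb @ (1.0 - p))
        # sums over individuals for p-update: (L, K)
        a_loc = p * (ga.T @ q)
        b_loc = (1.0 - p) * (gb.T @ q)

        q = a_sum + b_sum
        q /= q.sum(axis=1, keepdims=True)
        p = np.clip(a_loc / np.maximum(a_loc + b_loc, 1e-300), P_EPS, 1 - P_EPS)

        ll = _loglik(g0, mask, q, p)
        path.append(ll)
        if ll - ll_prev < tol and it > 1:
            ll_prev = ll
            break
        ll_prev = ll
    return AdmixtureFit(k, q, p, ll_prev, it, seed, path)


def match_columns(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Permute columns of ``q`` to best match ``q_ref`` (Hungarian matching).

    Resolves label switching between replicate fits before comparison.
    """
    k = q_ref.shape[1]
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -float(q_ref[:, i] @ q[:, j])
    _, cols = linear_sum_assignment(cost)
    return q[:, cols]


def evanno_delta_k(logliks_by_k: dict[int, list[float]]) -> DeltaKTable:
    """Evanno second-difference statistic over replicate log-likelihoods.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined only at interior K with >= 2 replicates and sd > 0; other K
    are flagged NaN.
    """
    ks = sorted(logliks_by_k)
    means = {k: float(np.mean(logliks_by_k[k])) for k in ks}
    sds = {
        k: float(np.std(logliks_by_k[k], ddof=1)) if len(logliks_by_k[k]) >= 2 else float("nan")
        for k in ks
    }
    delta: dict[int, float] = {}
    for k in ks:
        if k - 1 in means and k + 1 in means and np.isfinite(sds[k]) and sds[k] > 0:
            second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            delta[k] = second / sds[k]
        else:
            delta[k] = float("nan")
    return DeltaKTable(ks, means, sds, delta)


def run_structure_scan(
    genotypes: GenotypeMatrix | np.ndarray,
    k_range: range | list[int],
    replicates: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[dict[int, AdmixtureFit], DeltaKTable]:
    """Replicated admixture fits across a K range plus the delta-K table.

    Runs ``replicates`` EM fits per K with seeds ``seed + index`` and keeps
    the best-likelihood fit for each K; hard groups come from that fit's
    max-Q assignment. With a single K in the range the delta-K table is
    empty of defined values.
    """
    logliks: dict[int, list[float]] = {}
    best: dict[int, AdmixtureFit] = {}
    i = 0
    for k in k_range:
        logliks[k] = []
        for _ in range(replicates):
            fit = em_admixture(genotypes, k, seed=seed + i, max_iter=max_iter, tol=tol)
            logliks[k].append(fit.log_likelihood)
            if k not in best or fit.log_likelihood > best[k].log_likelihood:
                best[k] = fit
            i += 1
    return best, evanno_delta_k(logliks)
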