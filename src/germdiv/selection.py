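"""PCA-based comprehensive scoring and representative-accession selection.

Traits are z-scored and decomposed via the correlation-matrix eigenproblem;
components with eigenvalue > 1 are retained by default (Kaiser rule). Each
accession gets a comprehensive F score — the variance-weighted sum of its
retained component scores — and accessions are Ward-clustered on the
standardized traits. Representatives are then drawn per cluster in
descending F with quotas proportional to cluster size, followed by a repair
pass that guarantees every qualitative trait class present in the full
collection survives into the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .io import TraitMatrix

__all__ = [
    "PCAResult",
    "SelectionResult",
    "pca",
    "comprehensive_score",
    "cluster_phenotypes",
    "select_representatives",
]


@dataclass
class PCAResult:
    trait_names: list[str]
    loadings: np.ndarray  # trait x component eigenvectors
    eigenvalues: np.ndarray  # decreasing
    explained: np.ndarray  # proportions, sum to 1 over all components
    scores: np.ndarray  # accession x component
    n_retained: int  # components with eigenvalue > 1 (Kaiser)


@dataclass
class SelectionResult:
    accession_ids: list[str]
    labels: np.ndarray  # cluster label per accession (1..k)
    f_scores: np.ndarray
    selected: list[str]
    quotas: dict[int, int]


def _standardized(traits: TraitMatrix, include_qualitative: bool) -> tuple[np.ndarray, list[str]]:
    tm = traits if include_qualitative else traits.quantitative()
    X = tm.values.copy()
    # mean-impute missing cells, then z-score
    col_means = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_means, nan_idx[1])
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [tm.trait_names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant trait(s) cannot be standardized: {bad}")
    return (X - X.mean(axis=0)) / sd, list(tm.trait_names)


def pca(
    traits: TraitMatrix,
    standardize: bool = True,
    include_qualitative: bool = False,
) -> PCAResult:
    """Principal components of the trait table.

    With ``standardize`` (default) the correlation matrix of the
    (mean-imputed) quantitative traits is eigendecomposed; otherwise the
    covariance matrix of the raw values is used. Qualitative traits can be
    folded in as their graded integer codes with ``include_qualitative``.
    """
    Z, names = _standardized(traits, include_qualitative)
    if len(names) < 2:
        raise ValueError("PCA needs >= 2 traits")
    if Z.shape[0] < Z.shape[1]:
        warnings.warn("fewer accessions than traits; PCA still computed")
    if not standardize:
        tm = traits if include_qualitative else traits.quantitative()
        Z = tm.values - np.nanmean(tm.values, axis=0)
        Z = np.where(np.isnan(Z), 0.0, Z)
    C = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    explained = evals / evals.sum()
    scores = Z @ evecs
    n_retained = max(int((evals > 1.0).sum()), 1)
    return PCAResult(names, evecs, evals, explained, scores, n_retained)


def comprehensive_score(pca_result: PCAResult, n_components: int | None = None) -> np.ndarray:
    """Comprehensive F score: variance-weighted sum of component scores.

    F_i = sum_k w_k * score_ik with w_k the explained proportion of
    component k renormalized over the retained components. Higher F means a
    better overall phenotype under the component weighting.
    """
    if n_components is None:
        n_components = pca_result.n_retained
    if n_components == 0:
        raise ValueError("n_components must be >= 1")
    if n_components > pca_result.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    w = pca_result.explained[:n_components]
    w = w / w.sum()
    return pca_result.scores[:, :n_components] @ w


def cluster_phenotypes(
    traits: TraitMatrix, k: int, include_qualitative: bool = False
) -> np.ndarray:
    """Ward-linkage clustering of standardized traits, cut at k clusters.

    Deterministic given input order; labels are 1..k in scipy's leaf order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    Z, _ = _standardized(traits, include_qualitative)
    if k > Z.shape[0]:
        raise ValueError(f"k={k} exceeds n={Z.shape[0]} accessions")
    link = linkage(Z, method="ward")
    return fcluster(link, t=k, criterion="maxclust")


def _quotas(labels: np.ndarray, target_n: int) -> dict[int, int]:
    """Largest-remainder apportionment of target_n across clusters, min 1."""
    uniq, counts = np.unique(labels, return_counts=True)
    ideal = counts / counts.sum() * target_n
    base = np.maximum(np.floor(ideal).astype(int), 1)
    # trim any overshoot from the clusters with the smallest remainders
    rema = ideal - np.floor(ideal)
    while base.sum() > target_n:
        eligible = np.where(base > 1)[0]
        j = eligible[np.argmin(rema[eligible])]
        base[j] -= 1
        rema[j] = np.inf
    order = np.argsort(-rema)
    i = 0
    while base.sum() < target_n:
        j = order[i % len(order)]
        if base[j] < counts[j]:
            base[j] += 1
        i += 1
    return dict(zip(uniq.tolist(), base.tolist()))


def select_representatives(
    labels: np.ndarray,
    f_scores: np.ndarray,
    traits: TraitMatrix,
    target_n: int,
) -> SelectionResult:
    """Pick ``target_n`` representative accessions.

    Quota per cluster is proportional to cluster size (largest-remainder
    rounding, at least 1 each); within a cluster accessions are taken in
    descending F. A repair pass then swaps in, for any qualitative trait
    class present in the collection but absent from the selection, the
    highest-F carrier of that class, evicting the lowest-F selected
    accession whose removal does not break coverage.
    """
    ids = traits.accession_ids
    n = len(ids)
    labels = np.asarray(labels)
    f_scores = np.asarray(f_scores, dtype=float)
    k = np.unique(labels).size
    if target_n > n:
        raise ValueError("target_n exceeds number of accessions")
    if target_n < k:
        raise ValueError(f"target_n={target_n} below number of clusters {k}")
    quotas = _quotas(labels, target_n)

    selected_idx: list[int] = []
    for lab, quota in quotas.items():
        members = np.where(labels == lab)[0]
        ranked = members[np.argsort(-f_scores[members], kind="stable")]
        selected_idx.extend(ranked[:quota].tolist())

    qual_cols = [j for j, kd in enumerate(traits.kinds) if kd == "qualitative"]

    def classes_of(idx_list: list[int]) -> set[tuple[int, int]]:
        out = set()
        for i in idx_list:
            for j in qual_cols:
                v = traits.values[i, j]
                if not np.isnan(v):
                    out.add((j, int(v)))
        return out

    full_classes = classes_of(list(range(n)))
    sel = set(selected_idx)
    for j, cls in sorted(full_classes):
        if (j, cls) in classes_of(sorted(sel)):
            continue
        carriers = [
            i for i in range(n)
            if not np.isnan(traits.values[i, j]) and int(traits.values[i, j]) == cls
        ]
        best = max(carriers, key=lambda i: (f_scores[i], -i))
        sel.add(best)
        # evict the lowest-F member that is not a sole carrier of any class
        covered = classes_of(sorted(sel))
        for cand in sorted(sel - {best}, key=lambda i: (f_scores[i], -i)):
            if classes_of(sorted(sel - {cand})) == covered:
                sel.discard(cand)
                break
        else:
            # every member is a sole carrier: full coverage does not fit in
            # target_n, drop the lowest-F member anyway to hold the size
            sel.discard(min(sel - {best}, key=lambda i: (f_scores[i], -i)))
    sel_list = sorted(sel, key=lambda i: (-f_scores[i], i))
    return SelectionResult(
        list(ids), labels, f_scores, [ids[i] for i in sel_list], quotas
    )
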