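"""SSR population-genetics statistics.

Per-locus and per-population diversity parameters for codominant biallelic
SSR data: observed (Na) and effective (Ne = 1/sum p^2) allele numbers,
Shannon's index I = -sum p ln p, observed heterozygosity Ho, Nei's gene
diversity h = 1 - sum p^2, the unbiased expected heterozygosity
He = 2n/(2n-1) * h (Levene's correction with per-locus sample size), and
Botstein's polymorphism information content
PIC = 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2. Between-population divergence
uses Nei's (1972) standard genetic identity I_N = J_XY / sqrt(J_X J_Y),
with J terms averaged over loci before the ratio, and distance
D = -ln I_N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "LocusStats",
    "allele_frequencies",
    "effective_alleles",
    "shannon_locus",
    "heterozygosities",
    "pic",
    "frequencies_from_gene_diversity",
    "nei_identity_distance",
    "nei_identity_matrix",
    "locus_table",
    "population_table",
]

POOLED = "__pooled__"


@dataclass
class AlleleFrequencyTable:
    """locus -> group -> (frequency vector over [A, B], n non-missing)."""

    freqs: dict[str, dict[str, np.ndarray]]
    sizes: dict[str, dict[str, int]]

    def loci(self) -> list[str]:
        return list(self.freqs)

    def get(self, locus: str, group: str = POOLED) -> np.ndarray:
        return self.freqs[locus][group]

    def n(self, locus: str, group: str = POOLED) -> int:
        return self.sizes[locus][group]


@dataclass
class LocusStats:
    locus: str
    n: int
    na: int
    ne: float
    shannon_i: float
    ho: float
    he: float
    nei_h: float
    pic: float


def _locus_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_AB, n_BB) among non-missing calls at one locus."""
    return (
        int((calls == "AA").sum()),
        int((calls == "AB").sum()),
        int((calls == "BB").sum()),
    )


def allele_frequencies(
    genotypes: GenotypeMatrix, by_population: bool = False
) -> AlleleFrequencyTable:
    """Allele frequencies per locus, pooled and (optionally) per population.

    p(A) = (2 n_AA + n_AB) / (2 n) with n the number of individuals with a
    non-missing call; a locus with all calls missing in a group is omitted
    with a warning.
    """
    groups: dict[str, np.ndarray] = {POOLED: np.ones(genotypes.n_accessions, bool)}
    if by_population:
        if not genotypes.populations:
            raise ValueError("genotype matrix carries no population labels")
        for pop in genotypes.population_names:
            mask = np.array(
                [genotypes.populations[a] == pop for a in genotypes.accession_ids]
            )
            groups[pop] = mask
    freqs: dict[str, dict[str, np.ndarray]] = {}
    sizes: dict[str, dict[str, int]] = {}
    for j, locus in enumerate(genotypes.locus_names):
        col = genotypes.calls[:, j]
        for gname, mask in groups.items():
            sub = col[mask]
            naa, nab, nbb = _locus_counts(sub)
            n = naa + nab + nbb
            if n == 0:
                warnings.warn(f"locus {locus!r} all-missing in group {gname!r}; omitted")
                continue
            p = (2 * naa + nab) / (2 * n)
            freqs.setdefault(locus, {})[gname] = np.array([p, 1.0 - p])
            sizes.setdefault(locus, {})[gname] = n
    return AlleleFrequencyTable(freqs, sizes)


def _valid_freqs(freqs: np.ndarray) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("invalid allele frequency vector")
    return p / p.sum()


def effective_alleles(freqs: np.ndarray) -> float:
    """Effective number of alleles Ne = 1 / sum p_i^2."""
    p = _valid_freqs(freqs)
    return float(1.0 / (p**2).sum())


def shannon_locus(freqs: np.ndarray) -> float:
    """Shannon's diversity index I = -sum p_i ln p_i (nats)."""
    p = _valid_freqs(freqs)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def nei_gene_diversity(freqs: np.ndarray) -> float:
    """Nei's gene diversity h = 1 - sum p_i^2 (no sample-size correction)."""
    p = _valid_freqs(freqs)
    return float(1.0 - (p**2).sum())


def frequencies_from_gene_diversity(h: float) -> np.ndarray:
    """Invert a biallelic gene diversity h = 2pq to frequencies (p, q).

    Returns the (p >= q) solution p = (1 + sqrt(1 - 2h)) / 2. Only defined
    for h in [0, 0.5], the attainable range at a biallelic locus.
    """
    if not 0.0 <= h <= 0.5:
        raise ValueError(f"biallelic gene diversity must be in [0, 0.5], got {h}")
    p = (1.0 + math.sqrt(1.0 - 2.0 * h)) / 2.0
    return np.array([p, 1.0 - p])


def heterozygosities(
    calls: np.ndarray, freqs: np.ndarray | None = None, n: int | None = None
) -> tuple[float, float, float]:
    """(Ho, He, Nei_h) at one locus.

    Ho is the heterozygote fraction of non-missing calls; Nei_h = 1 - sum
    p^2; He applies Levene's unbiased correction 2n/(2n-1) with the
    locus-specific n. He is NaN (flagged undefined) when n < 2.
    """
    calls = np.asarray(calls, dtype=object)
    naa, nab, nbb = _locus_counts(calls)
    n_obs = naa + nab + nbb
    if n is None:
        n = n_obs
    if freqs is None:
        if n_obs == 0:
            raise ValueError("no non-missing calls")
        p = (2 * naa + nab) / (2 * n_obs)
        freqs = np.array([p, 1 - p])
    ho = nab / n_obs if n_obs else float("nan")
    h = nei_gene_diversity(freqs)
    he = (2 * n / (2 * n - 1)) * h if n >= 2 else float("nan")
    return float(ho), float(he), float(h)


def pic(freqs: np.ndarray) -> float:
    """Botstein's polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = _valid_freqs(freqs)
    s2 = (p**2).sum()
    # sum_{i<j} p_i^2 p_j^2 = ((sum p^2)^2 - sum p^4) / 2
    cross = (s2**2 - (p**4).sum()) / 2.0
    return float(1.0 - s2 - 2.0 * cross)


def pic_band_patterns(calls: np.ndarray) -> float:
    """PIC variant over genotype-pattern frequencies instead of alleles.

    Treats each distinct non-missing call (AA/AB/BB) as a "band pattern"
    and applies the Botstein sum to the pattern frequencies. Provided for
    comparison with dominant-scoring conventions; the allele-frequency
    :func:`pic` is the default everywhere.
    """
    calls = np.asarray(calls, dtype=object)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise ValueError("no non-missing calls")
    _, counts = np.unique(obs.astype(str), return_counts=True)
    return pic(counts / counts.sum())


def nei_identity_distance(
    freqs_x: dict[str, np.ndarray], freqs_y: dict[str, np.ndarray]
) -> tuple[float, float]:
    """Nei's (1972) standard genetic identity and distance for two groups.

    Over the loci shared by both frequency dictionaries:
    J_XY = mean_l sum_i x_il y_il, J_X = mean_l sum_i x_il^2, J_Y analogous;
    I_N = J_XY / sqrt(J_X J_Y) and D = -ln I_N. The J terms are averaged
    over loci before forming the ratio.
    """
    shared = [l for l in freqs_x if l in freqs_y]
    if not shared:
        raise ValueError("no shared loci between groups")
    jxy = np.mean([float(np.dot(freqs_x[l], freqs_y[l])) for l in shared])
    jx = np.mean([float(np.dot(freqs_x[l], freqs_x[l])) for l in shared])
    jy = np.mean([float(np.dot(freqs_y[l], freqs_y[l])) for l in shared])
    i_n = jxy / math.sqrt(jx * jy)
    if i_n <= 0:
        raise ValueError("non-positive identity; invalid frequencies")
    return float(i_n), float(-math.log(min(i_n, 1.0)))


def nei_identity_matrix(
    genotypes: GenotypeMatrix,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pairwise Nei identity and distance matrices between populations."""
    table = allele_frequencies(genotypes, by_population=True)
    pops = genotypes.population_names
    per_pop: dict[str, dict[str, np.ndarray]] = {p: {} for p in pops}
    for locus, groups in table.freqs.items():
        for pop in pops:
            if pop in groups:
                per_pop[pop][locus] = groups[pop]
    k = len(pops)
    ident = np.eye(k)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            i_n, d = nei_identity_distance(per_pop[pops[i]], per_pop[pops[j]])
            ident[i, j] = ident[j, i] = i_n
            dist[i, j] = dist[j, i] = d
    return pops, ident, dist


def _stats_for(calls: np.ndarray, locus: str) -> LocusStats:
    naa, nab, nbb = _locus_counts(calls)
    n = naa + nab + nbb
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    p = (2 * naa + nab) / (2 * n)
    freqs = np.array([p, 1 - p])
    na = int((freqs > 0).sum())
    ho, he, h = heterozygosities(calls, freqs, n)
    return LocusStats(
        locus, n, na, effective_alleles(freqs), shannon_locus(freqs), ho, he, h, pic(freqs)
    )


def locus_table(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pooled per-locus diversity parameters plus Mean and St.Dev rows.

    Columns mirror the conventional marker-report layout: Na, Ne, I, Ho,
    He, Nei, PIC; values rounded to 4 decimals on output.
    """
    rows = []
    for j, locus in enumerate(genotypes.locus_names):
        s = _stats_for(genotypes.calls[:, j], locus)
        rows.append(
            {"Primer": s.locus, "Na": s.na, "Ne": s.ne, "I": s.shannon_i,
             "Ho": s.ho, "He": s.he, "Nei": s.nei_h, "PIC": s.pic}
        )
    df = pd.DataFrame(rows)
    num = df.columns.drop("Primer")
    mean = df[num].mean()
    sd = df[num].std(ddof=1)
    df.loc[len(df)] = {"Primer": "Mean", **mean.to_dict()}
    df.loc[len(df)] = {"Primer": "St.Dev", **sd.to_dict()}
    df[num] = df[num].round(4)
    return df


def population_table(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-population means (+/- sd over loci) of the diversity parameters."""
    if not genotypes.populations:
        raise ValueError("genotype matrix carries no population labels")
    acc = np.array(genotypes.accession_ids)
    rows = []
    for pop in genotypes.population_names:
        mask = np.array([genotypes.populations[a] == pop for a in acc])
        stats = []
        for j, locus in enumerate(genotypes.locus_names):
            sub = genotypes.calls[mask, j]
            naa, nab, nbb = _locus_counts(sub)
            if naa + nab + nbb == 0:
                continue
            stats.append(_stats_for(sub, locus))
        def agg(attr: str) -> str:
            v = np.array([getattr(s, attr) for s in stats], dtype=float)
            return f"{np.nanmean(v):.4f}±{np.nanstd(v, ddof=1):.4f}"
        rows.append(
            {"Population": pop, "Na": agg("na"), "Ne": agg("ne"),
             "I": agg("shannon_i"), "Ho": agg("ho"), "He": agg("he"),
             "Nei": agg("nei_h"),
             "PIC": f"{np.nanmean([s.pic for s in stats]):.4f}"}
        )
    return pd.DataFrame(rows)
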