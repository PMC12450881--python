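"""Synthetic germplasm data with the statistical shape of the real study.

The generator emulates two unpublished matrices: a 1,582-accession x
22-trait phenotype table whose per-trait means, coefficients of variation
and qualitative class frequencies follow the published summary statistics,
and a 147-accession x 15-locus biallelic SSR genotype table partitioned
into six regional populations (Inner Mongolia, Northeast, Northern,
Northwest, Loess Plateau, Abroad) with sizes 14/30/10/25/63/5.

Population divergence follows the Balding-Nichols model: each population's
allele frequency is a Beta draw around the ancestral frequency with
variance F_div * p * (1 - p). Individual ancestry is one-hot by default or
Dirichlet(alpha) when an admixture concentration is given, and a
within-population inbreeding coefficient F_is controls the heterozygote
deficit (P(AB) = 2pq(1 - F_is)), which lets the generator reproduce both
the all-homozygote loci and the heterozygote-excess loci seen in real SSR
panels. All randomness flows from a single seed through numpy
SeedSequence spawning so each output is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BandMatrix,
    GenotypeMatrix,
    TraitMatrix,
    genotype_to_band,
    write_band_matrix,
    write_genotype_matrix,
    write_trait_matrix,
)

__all__ = [
    "QuantTrait",
    "QualTrait",
    "SynthesisConfig",
    "default_config",
    "gen_phenotypes",
    "gen_structured_genotypes",
    "gen_fixture_suite",
]

#: the 15 polymorphic SSR primers of the study panel
PANEL_LOCI = [
    "BLF-41", "BLF-4", "BLF-47", "BLF-8", "BLF-9", "BLF-51", "BLF-52",
    "BLF-58", "BLF-59", "BLF-61", "BLF-21", "BLF-66", "BLF-27", "BLF-79",
    "BLF-80",
]

#: the six regional populations with their panel sizes
PANEL_POPULATIONS = {
    "IMR": 14, "NER": 30, "NR": 10, "NWR": 25, "LPR": 63, "Abroad": 5,
}


@dataclass
class QuantTrait:
    name: str
    mean: float
    sd: float
    unit: str = ""
    nonneg: bool = False  # clip draws at 0 (distorts mean/CV slightly)


@dataclass
class QualTrait:
    name: str
    probs: tuple[float, ...]  # class probabilities for codes 0, 1, ...


# Published per-trait summaries of the 1,582-accession collection:
# (mean, CV%) for quantitative traits, class frequencies for qualitative.
_QUANT = [
    ("MSN", 6.34, 16.80, "nodes"),    # main stem nodes
    ("SH", 129.57, 20.09, "cm"),      # stem height
    ("SD", 6.79, 22.12, "mm"),        # stem diameter
    ("SWP", 32.15, 60.03, "g"),       # straw weight per plant
    ("TN", 2.26, 31.54, "tillers"),   # tiller number
    ("PL", 37.05, 21.43, "cm"),       # panicle length
    ("PWP", 9.97, 35.64, "g"),        # panicle weight per plant
    ("GWP", 7.20, 37.37, "g"),        # grain weight per plant
    ("TGW", 7.09, 14.94, "g"),        # thousand-grain weight
    ("GL", 2.85, 5.22, "mm"),         # grain length
    ("GW", 2.16, 6.61, "mm"),         # grain width
    ("LWR", 1.33, 5.48, ""),          # grain length-to-width ratio
]
_QUAL = [
    ("T", (0.595, 0.405)),                  # trichome: dense / sparse
    ("IC", (0.965, 0.035)),                 # inflorescence color: green / purple
    ("PT", (0.236, 0.526, 0.238)),          # panicle type
    ("AS", (0.233, 0.541, 0.226)),          # axis shape
    ("ID", (0.374, 0.417, 0.209)),          # inflorescence density
    ("PBB", (0.668, 0.332)),                # projection on branch base
    ("BH", (0.726, 0.274)),                 # branching habit
    ("ADB", (0.606, 0.394)),                # angle of divergence of branches
    ("BSL", (0.327, 0.327, 0.346)),         # branched spike length
    ("RS", (0.444, 0.308, 0.248)),          # shatter resistance
]

# Published pairwise correlations among eight core quantitative traits;
# unlisted pairs are uncorrelated.
_CORR_PAIRS = {
    ("TN", "MSN"): 0.07, ("TN", "PL"): -0.13,
    ("MSN", "SH"): 0.61, ("MSN", "PWP"): 0.37, ("MSN", "GWP"): 0.40,
    ("MSN", "SWP"): 0.44, ("MSN", "TGW"): 0.12,
    ("PL", "SH"): 0.16, ("PL", "PWP"): 0.14, ("PL", "GWP"): 0.10,
    ("PL", "SWP"): 0.10, ("PL", "TGW"): 0.27,
    ("SH", "PWP"): 0.59, ("SH", "GWP"): 0.58, ("SH", "SWP"): 0.70,
    ("SH", "TGW"): 0.37,
    ("PWP", "GWP"): 0.91, ("PWP", "SWP"): 0.56, ("PWP", "TGW"): 0.43,
    ("GWP", "SWP"): 0.54, ("GWP", "TGW"): 0.39,
    ("SWP", "TGW"): 0.41,
}


@dataclass
class SynthesisConfig:
    n_accessions: int = 1582
    quant_traits: list[QuantTrait] = field(default_factory=list)
    qual_traits: list[QualTrait] = field(default_factory=list)
    correlation: np.ndarray | None = None  # over quant traits, PSD
    n_loci: int = 15
    locus_names: list[str] = field(default_factory=lambda: list(PANEL_LOCI))
    population_sizes: dict[str, int] = field(
        default_factory=lambda: dict(PANEL_POPULATIONS)
    )
    f_div: float = 0.15  # Balding-Nichols divergence
    alpha: float | None = None  # Dirichlet admixture concentration; None = one-hot
    f_is: float = 0.7  # within-population inbreeding (heterozygote deficit)
    ancestral_freqs: np.ndarray | None = None  # per-locus allele-A freq; None = U(0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_div < 1.0:
            raise ValueError("f_div must be in (0, 1)")
        if not 0.0 <= self.f_is <= 1.0:
            raise ValueError("f_is must be in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if any(s < 1 for s in self.population_sizes.values()):
            raise ValueError("population sizes must be >= 1")
        for q in self.qual_traits:
            p = np.asarray(q.probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid class probabilities for {q.name!r}")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if not np.allclose(C, C.T):
                raise ValueError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("correlation matrix must be positive semi-definite")


def default_config(seed: int = 0) -> SynthesisConfig:
    """The study conditions: 1,582 x 22 phenotypes and 147 x 15 genotypes."""
    quant = [QuantTrait(n, m, m * cv / 100.0, u) for n, m, cv, u in _QUANT]
    qual = [QualTrait(n, p) for n, p in _QUAL]
    names = [q.name for q in quant]
    C = np.eye(len(names))
    for (a, b), r in _CORR_PAIRS.items():
        i, j = names.index(a), names.index(b)
        C[i, j] = C[j, i] = r
    # repair tiny negative eigenvalues from assembling printed pair values
    w, v = np.linalg.eigh(C)
    if w.min() < 0:
        C = (v * np.maximum(w, 1e-6)) @ v.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    # ancestral allele frequencies chosen so each locus's gene diversity
    # matches the published panel value (h inverted to the p >= q root)
    from .popgen import frequencies_from_gene_diversity
    from .reference import LOCUS_NEI_H

    anc = np.array(
        [frequencies_from_gene_diversity(LOCUS_NEI_H[l])[0] for l in PANEL_LOCI]
    )
    return SynthesisConfig(
        quant_traits=quant, qual_traits=qual, correlation=C,
        ancestral_freqs=anc, seed=seed,
    )


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=(stream,)))


def gen_phenotypes(config: SynthesisConfig) -> TraitMatrix:
    """Accession x trait table drawn from the configured distributions.

    Quantitative traits come from a multivariate normal with the requested
    means, sds and correlation matrix (optionally clipped at zero for
    traits flagged nonnegative); qualitative traits are independent
    categorical draws. Identical config and seed give identical output.
    """
    rng = _rng(config.seed, 1)
    n = config.n_accessions
    nq = len(config.quant_traits)
    C = config.correlation if config.correlation is not None else np.eye(nq)
    C = np.asarray(C, dtype=float)
    if C.shape != (nq, nq):
        raise ValueError("correlation matrix shape must match quantitative traits")
    means = np.array([t.mean for t in config.quant_traits])
    sds = np.array([t.sd for t in config.quant_traits])
    L = np.linalg.cholesky(C + 1e-12 * np.eye(nq)) if nq else np.empty((0, 0))
    z = rng.standard_normal((n, nq)) @ L.T
    X = means + z * sds
    for j, t in enumerate(config.quant_traits):
        if t.nonneg:
            X[:, j] = np.maximum(X[:, j], 0.0)
    cols = [X]
    for q in config.qual_traits:
        draws = rng.choice(len(q.probs), size=n, p=np.asarray(q.probs, float))
        cols.append(draws[:, None].astype(float))
    values = np.hstack(cols) if cols else np.empty((n, 0))
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    names = [t.name for t in config.quant_traits] + [q.name for q in config.qual_traits]
    kinds = ["quantitative"] * nq + ["qualitative"] * len(config.qual_traits)
    units = [t.unit for t in config.quant_traits] + [""] * len(config.qual_traits)
    return TraitMatrix(ids, names, kinds, values, units)


def gen_structured_genotypes(
    config: SynthesisConfig,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Structured SSR genotypes plus the generating truth (Q, P).

    Ancestral frequencies ~ Uniform(0.1, 0.9); per-population frequencies
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols with F = f_div);
    ancestry rows are one-hot, or Dirichlet(alpha) over the populations
    when an admixture concentration is configured. Genotypes are drawn
    from each individual's mixture allele frequency f with
    P(AB) = 2f(1-f)(1-F_is) and the matching homozygote excess.
    """
    rng = _rng(config.seed, 2)
    pops = list(config.population_sizes)
    k = len(pops)
    sizes = [config.population_sizes[p] for p in pops]
    n = int(sum(sizes))
    l = config.n_loci
    loci = list(config.locus_names)
    if len(loci) != l:
        raise ValueError("locus_names length must equal n_loci")

    f = config.f_div
    if config.ancestral_freqs is not None:
        anc = np.asarray(config.ancestral_freqs, dtype=float)
        if anc.shape != (l,):
            raise ValueError("ancestral_freqs length must equal n_loci")
        anc = np.clip(anc, 1e-3, 1 - 1e-3)
    else:
        anc = rng.uniform(0.1, 0.9, size=l)
    a = anc * (1 - f) / f
    b = (1 - anc) * (1 - f) / f
    P = rng.beta(a[None, :], b[None, :], size=(k, l))  # pop x locus
    P = np.clip(P, 1e-4, 1 - 1e-4)

    Q = np.zeros((n, k))
    pop_of: list[str] = []
    row = 0
    for ki, (pop, sz) in enumerate(zip(pops, sizes)):
        for _ in range(sz):
            if config.alpha is None:
                Q[row, ki] = 1.0
            else:
                conc = np.full(k, config.alpha)
                conc[ki] += 1.0  # anchor each individual to its home population
                Q[row] = rng.dirichlet(conc)
            pop_of.append(pop)
            row += 1

    mix = Q @ P  # individual x locus allele-A frequency
    het = 2 * mix * (1 - mix) * (1 - config.f_is)
    p_aa = mix**2 + config.f_is * mix * (1 - mix)
    u = rng.random((n, l))
    calls = np.where(u < p_aa, "AA", np.where(u < p_aa + het, "AB", "BB")).astype(object)

    ids = [f"G{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(ids, loci, calls, dict(zip(ids, pop_of)))
    return gm, Q, P.T  # P returned as locus x population


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def gen_fixture_suite(seed: int, out_dir: str | Path) -> dict[str, str]:
    """Write the deterministic fixture bundle and return its checksums.

    Produces: the 1,582 x 22 trait table with its schema, the 147 x 15
    genotype table with population labels and the derived band matrix, a
    20-accession screening panel of phenotypically extreme accessions, and
    metadata for the genotyped panel. Byte-identical for identical seeds;
    a manifest.json records each file's sha256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed)

    traits = gen_phenotypes(cfg)
    write_trait_matrix(traits, out / "traits.csv")
    pd.DataFrame(
        {"trait": traits.trait_names, "kind": traits.kinds, "unit": traits.units}
    ).to_csv(out / "schema.csv", index=False)

    gm, _, _ = gen_structured_genotypes(cfg)
    write_genotype_matrix(gm, out / "genotypes.csv")
    pd.DataFrame(
        {"accession": gm.accession_ids,
         "population": [gm.populations[a] for a in gm.accession_ids]}
    ).to_csv(out / "populations.csv", index=False)
    write_band_matrix(genotype_to_band(gm), out / "bands.csv")

    # screening panel: 20 phenotypically extreme accessions (largest
    # deviation from the collection mean across standardized traits)
    qt = traits.quantitative()
    Z = (qt.values - np.nanmean(qt.values, axis=0)) / np.nanstd(qt.values, axis=0)
    extremity = np.nanmax(np.abs(Z), axis=1)
    top = np.argsort(-extremity, kind="stable")[:20]
    screen = TraitMatrix(
        [traits.accession_ids[i] for i in sorted(top)],
        traits.trait_names, traits.kinds, traits.values[sorted(top)], traits.units,
    )
    write_trait_matrix(screen, out / "screening_panel.csv")

    classes = ["landrace", "cultivar"]
    meta = pd.DataFrame(
        {
            "accession": gm.accession_ids,
            "Name": [f"Variety-{i + 1}" for i in range(gm.n_accessions)],
            "Unicode": [f"PM{seed % 1000:03d}{i + 1:04d}" for i in range(gm.n_accessions)],
            "Source": [gm.populations[a] for a in gm.accession_ids],
            "Classification": [classes[i % 2] for i in range(gm.n_accessions)],
        }
    )
    meta.to_csv(out / "metadata.csv", index=False)

    files = sorted(p.name for p in out.iterdir() if p.suffix == ".csv")
    manifest = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
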