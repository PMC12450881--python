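# germdiv

Germplasm diversity analysis for crop genebank collections, built around a
proso millet (*Panicum miliaceum* L.) survey design: a large phenotyped
collection (~1,582 accessions × 22 agronomic, yield and grain traits) is
profiled and distilled to a representative panel (147 accessions), which is
then genotyped at a small set of biallelic, codominant SSR markers
(15 primers), analyzed for population-genetic structure, and assigned
digital DNA fingerprints / QR-ready molecular IDs.

The package is aimed at genebank curators and crop-diversity researchers
who need the full chain — trait diversity statistics, accession selection,
marker statistics, clustering, structure inference, fingerprinting — as
reusable, tested functions rather than a chain of GUI tools.

## What it computes

**Phenotypic diversity** (`germdiv.pheno`)
- Shannon–Weaver index H′ = −Σ pᵢ ln pᵢ (nats) over trait classes;
  quantitative traits are discretized into 10 classes with boundaries at
  mean + k·sd, k = −2, −1.5, …, +2.
- Coefficient of variation CV = 100·sd/mean, descriptive statistics, and
  pairwise-complete Pearson/Spearman trait correlations with two-sided
  p-values.

**PCA scoring and selection** (`germdiv.selection`)
- PCA via the correlation-matrix eigenproblem of z-scored traits, Kaiser
  retention (eigenvalue > 1).
- Comprehensive score F = Σₖ wₖ·scoreₖ with wₖ the renormalized explained
  variance of retained component k; Ward clustering; per-cluster
  proportional quotas with a repair pass guaranteeing every qualitative
  trait class survives into the selection.

**SSR population genetics** (`germdiv.popgen`)
- Allele frequencies p = (2n_AA + n_AB)/2n; Na; Ne = 1/Σpᵢ²;
  Shannon I = −Σ pᵢ ln pᵢ; Ho; Nei's gene diversity h = 1 − Σpᵢ²;
  unbiased He = 2n/(2n−1)·h (Levene); Botstein's
  PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ².
- Nei (1972) standard genetic identity I_N = J_XY/√(J_X·J_Y) with J terms
  averaged over loci, and distance D = −ln I_N.

**Trees and marker PCA** (`germdiv.trees`)
- Dice (Nei & Li) and simple-matching band distances; UPGMA with
  deterministic lexicographic tie-breaking and merge heights d/2;
  k-group tree cutting; PCA of the centered binary band matrix.

**Population structure** (`germdiv.admixture`)
- Maximum-likelihood admixture model (the Structure generative model, EM
  point estimation): individual ancestries Q and source allele
  frequencies P maximizing
  Σᵢₗ [gᵢₗ ln(Σₖ qᵢₖ pₖₗ) + (2 − gᵢₗ) ln(Σₖ qᵢₖ(1 − pₖₗ))];
  replicate scans over K and Evanno's
  ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)).

**DNA fingerprints** (`germdiv.fingerprint`)
- 2-bits-per-primer fingerprint codes (12 primers → 24 characters), greedy
  minimal discriminating primer-set selection, and deterministic
  Name/Unicode/Source/Classification ID payload text for any QR encoder.

**Synthetic data** (`germdiv.synth`)
- A generator reproducing the study conditions (trait means/CVs/class
  frequencies; Balding–Nichols population divergence with per-locus
  ancestral frequencies calibrated to the published gene diversities;
  inbreeding-controlled heterozygosity), returning the generating truth
  for parameter-recovery tests.

## Worked example

```python
>>> import germdiv as gd

# Shannon-Weaver index of a qualitative trait scored green 96.5% / purple 3.5%
>>> gd.shannon_weaver([0.965, 0.035])
0.1517144790378862          # rounds to 0.15 nats: a nearly fixed trait

# locus statistics implied by a gene diversity of 0.4904 (locus BLF-79)
>>> p = gd.frequencies_from_gene_diversity(0.4904)  # -> (0.5693, 0.4307)
>>> round(gd.effective_alleles(p), 4), round(gd.shannon_locus(p), 4)
(1.9623, 0.6835)            # nearly the biallelic maximum of 2 and ln 2

# full pipeline on a synthetic 147 x 15 panel in six regional populations
>>> gm, Q, P = gd.gen_structured_genotypes(gd.default_config(seed=7))
>>> gd.locus_table(gm).head(3)
   Primer   Na      Ne       I      Ho      He     Nei     PIC
0  BLF-41  2.0  1.3673  0.4394  0.0476  0.2695  0.2686  0.2325
1   BLF-4  2.0  1.0850  0.1705  0.0136  0.0786  0.0783  0.0752
2  BLF-47  2.0  1.2737  0.3718  0.0544  0.2156  0.2149  0.1918
```

The first locus segregates moderately (Ne ≈ 1.37 effective alleles, gene
diversity 0.27); the second is close to fixation. The low Ho against Nei's
h reflects the strong inbreeding typical of a selfing crop, which the
generator controls through `f_is`.

A command-line interface mirrors the library:

```bash
germdiv synth --seed 1 --out fixtures/
germdiv pheno --traits fixtures/traits.csv --schema fixtures/schema.csv \
              --out summaries.csv --corr corr.csv
germdiv select --traits fixtures/traits.csv --schema fixtures/schema.csv \
               --k 5 --target 147 --out selection.csv
germdiv popgen --geno fixtures/genotypes.csv --pops fixtures/populations.csv \
               --out locus_stats.csv --identity identity.csv
germdiv tree --bands fixtures/bands.csv --cut 4 --out tree.nwk
germdiv structure --geno fixtures/genotypes.csv --kmin 1 --kmax 5 --reps 5 \
                  --seed 42 --out qdir/
germdiv fingerprint --bands fixtures/bands.csv --meta fixtures/metadata.csv \
                    --out ids.csv
```

## Layout

```
src/germdiv/
  io.py           data model (trait/band/genotype/distance matrices) and CSV/Newick I/O
  pheno.py        Shannon-Weaver indices, CVs, correlations
  selection.py    PCA, comprehensive F score, Ward clustering, selection
  popgen.py       locus statistics, Nei identity/distance, report tables
  trees.py        band distances, UPGMA, tree cutting, marker PCA
  admixture.py    EM admixture, Evanno delta-K, structure scans
  fingerprint.py  fingerprint codes, minimal primer sets, ID payloads
  synth.py        synthetic phenotype/genotype generator, fixture bundles
  reference.py    published summary statistics used by the consistency checks
  cli.py          click command-line interface
```

See `docs/methods.md` for the statistical models, default parameters, and
known limitations.
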