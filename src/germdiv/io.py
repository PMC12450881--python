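"""Shared data model and tabular/tree I/O.

All tables are comma-separated UTF-8 with a header row and the accession
identifier in the first column; "." is the decimal mark. Missing values are
accepted as empty cells or ``NA`` on read and always written back as ``NA``.

SSR primer names appear in the literature both hyphenated (``BLF-41``) and
unhyphenated (``BLF41``); the two forms denote the same primer, so locus
names are compared after hyphen stripping via :func:`canonical_locus`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "GenotypeMatrix",
    "BandMatrix",
    "DistanceMatrix",
    "TreeNode",
    "canonical_locus",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_band_matrix",
    "write_band_matrix",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "band_to_genotype",
    "genotype_to_band",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_newick",
]

MISSING = "missing"
GENOTYPES = ("AA", "AB", "BB", MISSING)

#: band-slot pair -> codominant call (two slots per biallelic SSR primer)
BAND_TO_CALL = {(1, 0): "AA", (0, 1): "BB", (1, 1): "AB", (0, 0): MISSING}
CALL_TO_BAND = {v: k for k, v in BAND_TO_CALL.items() if v != MISSING}


def canonical_locus(name: str) -> str:
    """Normalize a locus/primer name by removing hyphens (BLF-41 == BLF41)."""
    return name.replace("-", "")


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for a in ids:
        if a in seen:
            raise ValueError(f"duplicate accession id: {a!r}")
        seen.add(a)


@dataclass
class TraitMatrix:
    """Accession x trait table with per-trait kind and units.

    Quantitative traits hold real values; qualitative traits hold small
    nonnegative integer class codes. Missing values are ``NaN`` in
    ``values`` — a qualitative code of 0 is a real class, never a missing
    marker.
    """

    accession_ids: list[str]
    trait_names: list[str]
    kinds: list[Literal["quantitative", "qualitative"]]
    values: np.ndarray  # float array, NaN = missing
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique_ids(self.accession_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accession_ids), len(self.trait_names)):
            raise ValueError("values shape does not match ids/traits")
        if len(self.kinds) != len(self.trait_names):
            raise ValueError("one kind per trait required")
        for k in self.kinds:
            if k not in ("quantitative", "qualitative"):
                raise ValueError(f"unknown trait kind {k!r}")
        if not self.units:
            self.units = [""] * len(self.trait_names)
        for j, k in enumerate(self.kinds):
            if k == "qualitative":
                col = self.values[:, j]
                ok = np.isnan(col) | ((col >= 0) & (col == np.floor(col)))
                if not ok.all():
                    raise ValueError(
                        f"qualitative trait {self.trait_names[j]!r} has "
                        "non-integer or negative codes"
                    )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(trait)]

    def quantitative(self) -> "TraitMatrix":
        """Sub-matrix of the quantitative traits only."""
        idx = [j for j, k in enumerate(self.kinds) if k == "quantitative"]
        return TraitMatrix(
            self.accession_ids,
            [self.trait_names[j] for j in idx],
            ["quantitative"] * len(idx),
            self.values[:, idx],
            [self.units[j] for j in idx],
        )


@dataclass
class BandMatrix:
    """Binary electrophoresis band scores, exactly two band slots per primer."""

    accession_ids: list[str]
    primer_names: list[str]
    bands: np.ndarray  # (n_accessions, 2 * n_primers) in {0, 1}

    def __post_init__(self) -> None:
        _check_unique_ids(self.accession_ids)
        self.bands = np.asarray(self.bands, dtype=int)
        expected = (len(self.accession_ids), 2 * len(self.primer_names))
        if self.bands.shape != expected:
            raise ValueError(
                f"band matrix must have 2 slots per primer: expected shape "
                f"{expected}, got {self.bands.shape}"
            )
        if not np.isin(self.bands, (0, 1)).all():
            raise ValueError("band entries must be 0 or 1")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def primer_slots(self, primer: str) -> np.ndarray:
        """The two band-slot columns of one primer."""
        names = [canonical_locus(p) for p in self.primer_names]
        try:
            j = names.index(canonical_locus(primer))
        except ValueError:
            raise KeyError(f"unknown primer {primer!r}") from None
        return self.bands[:, 2 * j : 2 * j + 2]


@dataclass
class GenotypeMatrix:
    """Codominant SSR calls (AA/AB/BB/missing) with population labels."""

    accession_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray  # object array of GENOTYPES strings
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique_ids(self.accession_ids)
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.accession_ids), len(self.locus_names)):
            raise ValueError("calls shape does not match ids/loci")
        bad = set(self.calls.ravel()) - set(GENOTYPES)
        if bad:
            raise ValueError(f"invalid genotype call(s): {sorted(bad)}")
        if self.populations:
            extra = set(self.populations) - set(self.accession_ids)
            missing_ids = set(self.accession_ids) - set(self.populations)
            if extra or missing_ids:
                raise ValueError(
                    "population labels must form a partition of accessions; "
                    f"unlabelled={sorted(missing_ids)[:5]}, stray={sorted(extra)[:5]}"
                )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def population_names(self) -> list[str]:
        seen: list[str] = []
        for a in self.accession_ids:
            p = self.populations.get(a)
            if p is not None and p not in seen:
                seen.append(p)
        return seen

    def dosage(self) -> np.ndarray:
        """Allele-A dosage coding: AA=2, AB=1, BB=0, missing=NaN."""
        code = {"AA": 2.0, "AB": 1.0, "BB": 0.0, MISSING: np.nan}
        out = np.empty(self.calls.shape, dtype=float)
        for g, v in code.items():
            out[self.calls == g] = v
        return out

    def subset(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accession_ids.index(a) for a in accessions]
        pops = {a: self.populations[a] for a in accessions} if self.populations else {}
        return GenotypeMatrix(list(accessions), self.locus_names, self.calls[idx], pops)


@dataclass
class DistanceMatrix:
    """Square symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be square over labels")
        if np.isnan(self.matrix).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# Trees (UPGMA output); serialized as Newick, round-trippable with dendropy.


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry labels, internal nodes a merge height."""

    label: str | None = None
    height: float = 0.0  # distance from this node down to any leaf below it
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label or "" for l in self.leaves()]


def write_newick(tree: TreeNode) -> str:
    """Serialize a rooted tree with branch lengths to a Newick string.

    Branch lengths are parent height minus child height; every leaf must be
    labelled. A single unlabelled-leaf tree is rejected.
    """

    def blen(x: float) -> str:
        s = f"{x:.6f}".rstrip("0").rstrip(".")
        return s if s else "0"

    def fmt(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            if not node.label:
                raise ValueError("unlabeled leaf in tree")
            body = node.label
        else:
            body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
            if node.label:
                body += node.label
        if parent_height is None:
            return body
        return f"{body}:{blen(parent_height - node.height)}"

    return fmt(tree, None) + ";"


# ---------------------------------------------------------------------------
# CSV readers/writers


def read_trait_matrix(
    path: str | Path, schema: Mapping[str, str], units: Mapping[str, str] | None = None
) -> TraitMatrix:
    """Read an accession x trait CSV.

    ``schema`` maps every trait column to ``"quantitative"`` or
    ``"qualitative"``. Empty cells and ``NA`` are missing. Duplicated
    accession ids and unparseable cells are hard errors naming the culprit.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    ids = df.iloc[:, 0].astype(str).tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate accession id: {dup.iloc[0]!r}")
    traits = list(df.columns[1:])
    for t in traits:
        if t not in schema:
            raise ValueError(f"schema does not cover trait column {t!r}")
    kinds = [schema[t] for t in traits]
    values = np.full((len(ids), len(traits)), np.nan)
    for j, t in enumerate(traits):
        for i, raw in enumerate(df[t].tolist()):
            cell = raw.strip()
            if cell in ("", "NA"):
                continue
            try:
                v = float(cell)
                if kinds[j] == "qualitative" and (v < 0 or v != int(v)):
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"unparseable {kinds[j]} value {cell!r} at row {ids[i]!r}, "
                    f"column {t!r}"
                ) from None
            values[i, j] = v
    unit_list = [units.get(t, "") for t in traits] if units else [""] * len(traits)
    return TraitMatrix(ids, traits, kinds, values, unit_list)


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    rows = []
    for i, a in enumerate(tm.accession_ids):
        row: dict[str, object] = {"accession": a}
        for j, t in enumerate(tm.trait_names):
            v = tm.values[i, j]
            if np.isnan(v):
                row[t] = "NA"
            elif tm.kinds[j] == "qualitative":
                row[t] = int(v)
            else:
                row[t] = repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band CSV with two columns per primer, named ``<primer>.1/.2``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    ids = df.iloc[:, 0].astype(str).tolist()
    cols = list(df.columns[1:])
    primers: list[str] = []
    for c in cols:
        stem = c.rsplit(".", 1)[0]
        if stem not in primers:
            primers.append(stem)
    for p in primers:
        slots = [c for c in cols if c.rsplit(".", 1)[0] == p]
        if len(slots) != 2:
            raise ValueError(f"primer {p!r} has {len(slots)} band slots, expected 2")
    bands = df[cols].astype(int).to_numpy()
    return BandMatrix(ids, primers, bands)


def write_band_matrix(bm: BandMatrix, path: str | Path) -> None:
    cols = {"accession": bm.accession_ids}
    for j, p in enumerate(bm.primer_names):
        cols[f"{p}.1"] = bm.bands[:, 2 * j]
        cols[f"{p}.2"] = bm.bands[:, 2 * j + 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_genotype_matrix(
    path: str | Path, populations: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    ids = df.iloc[:, 0].astype(str).tolist()
    loci = list(df.columns[1:])
    calls = df[loci].replace({"": MISSING, "NA": MISSING}).to_numpy(dtype=object)
    pops = dict(populations) if populations else {}
    return GenotypeMatrix(ids, loci, calls, pops)


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.calls, columns=gm.locus_names)
    df.insert(0, "accession", gm.accession_ids)
    df = df.replace({MISSING: "NA"})
    df.to_csv(path, index=False)


def band_to_genotype(
    bands: BandMatrix, populations: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Convert band-slot pairs to codominant calls.

    Mapping per primer: (1,0) -> AA, (0,1) -> BB, (1,1) -> AB (both alleles
    amplified), (0,0) -> missing (no amplification). Locus names inherit the
    primer names.
    """
    n, p = bands.n_accessions, len(bands.primer_names)
    calls = np.empty((n, p), dtype=object)
    for j in range(p):
        pair = bands.bands[:, 2 * j : 2 * j + 2]
        for i in range(n):
            calls[i, j] = BAND_TO_CALL[(int(pair[i, 0]), int(pair[i, 1]))]
    pops = dict(populations) if populations else {}
    return GenotypeMatrix(list(bands.accession_ids), list(bands.primer_names), calls, pops)


def genotype_to_band(gm: GenotypeMatrix) -> BandMatrix:
    """Inverse of :func:`band_to_genotype`; missing calls map to (0, 0)."""
    n, p = gm.n_accessions, len(gm.locus_names)
    bands = np.zeros((n, 2 * p), dtype=int)
    for j in range(p):
        for i in range(n):
            call = gm.calls[i, j]
            if call != MISSING:
                bands[i, 2 * j : 2 * j + 2] = CALL_TO_BAND[call]
    return BandMatrix(list(gm.accession_ids), list(gm.locus_names), bands)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix([str(l) for l in df.index], df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(path)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Accession metadata table (Name, Unicode, Source, Classification)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0], drop=False)
    return df
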