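"""Published summary statistics of the proso millet germplasm survey.

These are the printed report-level numbers of the study this package
re-implements — per-locus gene diversities and derived indices for the
15-primer SSR panel, the regional Nei identity matrix, and the
inflorescence-color class frequencies of the 1,582-accession phenotype
collection. The raw accession-level matrices were never deposited, so
these summaries are the only published ground truth; the self-consistency
checks recompute each derived column from the gene diversities alone.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LOCUS_NEI_H",
    "LOCUS_NE",
    "LOCUS_I",
    "MEAN_NE",
    "POPULATIONS",
    "IDENTITY_UPPER",
    "DISTANCE_LOWER",
    "INFLORESCENCE_COLOR_FREQS",
    "identity_matrix",
]

#: per-locus Nei gene diversity h = 1 - sum p^2 (pooled over 147 accessions)
LOCUS_NEI_H = {
    "BLF-41": 0.2580, "BLF-4": 0.1605, "BLF-47": 0.2188, "BLF-8": 0.2355,
    "BLF-9": 0.1017, "BLF-51": 0.0571, "BLF-52": 0.3227, "BLF-58": 0.0506,
    "BLF-59": 0.1298, "BLF-61": 0.1663, "BLF-21": 0.0260, "BLF-66": 0.1475,
    "BLF-27": 0.4342, "BLF-79": 0.4904, "BLF-80": 0.1031,
}

#: per-locus effective allele number as printed
LOCUS_NE = {
    "BLF-41": 1.3478, "BLF-4": 1.1912, "BLF-47": 1.2800, "BLF-8": 1.3081,
    "BLF-9": 1.1133, "BLF-51": 1.0606, "BLF-52": 1.4764, "BLF-58": 1.0533,
    "BLF-59": 1.1492, "BLF-61": 1.1995, "BLF-21": 1.0267, "BLF-66": 1.1730,
    "BLF-27": 1.7676, "BLF-79": 1.9625, "BLF-80": 1.1150,
}

#: per-locus Shannon index as printed
LOCUS_I = {
    "BLF-41": 0.4265, "BLF-4": 0.2979, "BLF-47": 0.3768, "BLF-8": 0.3983,
    "BLF-9": 0.2095, "BLF-51": 0.1327, "BLF-52": 0.5035, "BLF-58": 0.1205,
    "BLF-59": 0.2530, "BLF-61": 0.3061, "BLF-21": 0.0701, "BLF-66": 0.2791,
    "BLF-27": 0.6259, "BLF-79": 0.6836, "BLF-80": 0.2117,
}

#: printed mean effective allele number over the 15 loci
MEAN_NE = 1.2816

POPULATIONS = ["IMR", "NER", "NR", "NWR", "LPR", "Abroad"]

#: Nei (1972) genetic identity, upper triangle by population pair
IDENTITY_UPPER = {
    ("IMR", "NER"): 0.9776, ("IMR", "NR"): 0.9590, ("IMR", "NWR"): 0.9865,
    ("IMR", "LPR"): 0.9636, ("IMR", "Abroad"): 0.8204,
    ("NER", "NR"): 0.9617, ("NER", "NWR"): 0.9901, ("NER", "LPR"): 0.9853,
    ("NER", "Abroad"): 0.8138,
    ("NR", "NWR"): 0.9781, ("NR", "LPR"): 0.9751, ("NR", "Abroad"): 0.8218,
    ("NWR", "LPR"): 0.9866, ("NWR", "Abroad"): 0.8123,
    ("LPR", "Abroad"): 0.8529,
}

#: Nei genetic distance D = -ln I, lower triangle as printed
DISTANCE_LOWER = {
    ("IMR", "NER"): 0.0227, ("IMR", "NR"): 0.0418, ("IMR", "NWR"): 0.0136,
    ("IMR", "LPR"): 0.0371, ("IMR", "Abroad"): 0.1980,
    ("NER", "NR"): 0.0391, ("NER", "NWR"): 0.0099, ("NER", "LPR"): 0.0148,
    ("NER", "Abroad"): 0.2060,
    ("NR", "NWR"): 0.0221, ("NR", "LPR"): 0.0252, ("NR", "Abroad"): 0.1963,
    ("NWR", "LPR"): 0.0135, ("NWR", "Abroad"): 0.2079,
    ("LPR", "Abroad"): 0.1591,
}

#: class frequencies of inflorescence color (green, purple) over 1,582
INFLORESCENCE_COLOR_FREQS = np.array([0.965, 0.035])


def identity_matrix() -> np.ndarray:
    """The published identity values as a symmetric matrix (diagonal 1)."""
    k = len(POPULATIONS)
    m = np.eye(k)
    for (a, b), v in IDENTITY_UPPER.items():
        i, j = POPULATIONS.index(a), POPULATIONS.index(b)
        m[i, j] = m[j, i] = v
    return m
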