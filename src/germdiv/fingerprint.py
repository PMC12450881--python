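"""DNA fingerprint codes and QR-ready molecular-ID payloads.

An accession's fingerprint is the concatenation of its two band-presence
bits per SSR primer in a fixed primer order — 12 primers give the
24-character binary string used as its DNA molecular ID. A greedy
pair-splitting routine selects a small primer subset that distinguishes
the maximum number of accessions with the minimum number of primers, and
the ID payload augments the code with Name, Unicode, Source and
Classification fields as deterministic text for any QR encoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import BandMatrix, canonical_locus

__all__ = [
    "FingerprintCode",
    "IDPayload",
    "encode_fingerprint",
    "decode_fingerprint",
    "minimal_primer_set",
    "build_id_payload",
    "parse_id_payload",
]

#: fixed primer concatenation order of the 12-primer molecular ID
DEFAULT_PRIMER_ORDER = [
    "BLF41", "BLF4", "BLF47", "BLF8", "BLF9", "BLF52",
    "BLF58", "BLF21", "BLF66", "BLF27", "BLF79", "BLF80",
]

PAYLOAD_FIELDS = ("Name", "Unicode", "Source", "Classification")


@dataclass
class FingerprintCode:
    accession_id: str
    primer_order: list[str]
    code: str  # 2 chars per primer, '0'/'1'

    def __post_init__(self) -> None:
        if len(self.code) != 2 * len(self.primer_order):
            raise ValueError("code length must be 2 x number of primers")
        if set(self.code) - {"0", "1"}:
            raise ValueError("code characters must be '0' or '1'")


@dataclass
class IDPayload:
    name: str
    unicode: str
    source: str
    classification: str
    code: str

    def text(self) -> str:
        return (
            f"Name: {self.name}\n"
            f"Unicode: {self.unicode}\n"
            f"Source: {self.source}\n"
            f"Classification: {self.classification}\n"
            f"Code: {self.code}"
        )


def encode_fingerprint(
    bands: BandMatrix, primer_order: Sequence[str] | None = None
) -> list[FingerprintCode]:
    """Fingerprint code per accession in the given primer order.

    Unknown primers are an error; the default order is the 12-primer
    molecular-ID order, applied only when those primers are all present.
    """
    if primer_order is None:
        have = {canonical_locus(p) for p in bands.primer_names}
        if all(canonical_locus(p) in have for p in DEFAULT_PRIMER_ORDER):
            primer_order = DEFAULT_PRIMER_ORDER
        else:
            primer_order = list(bands.primer_names)
    slots = [bands.primer_slots(p) for p in primer_order]  # KeyError -> unknown
    out = []
    for i, acc in enumerate(bands.accession_ids):
        code = "".join(f"{s[i, 0]}{s[i, 1]}" for s in slots)
        out.append(FingerprintCode(acc, list(primer_order), code))
    return out


def decode_fingerprint(code: FingerprintCode) -> dict[str, tuple[int, int]]:
    """Positional split of a code back to per-primer band pairs."""
    return {
        p: (int(code.code[2 * j]), int(code.code[2 * j + 1]))
        for j, p in enumerate(code.primer_order)
    }


def minimal_primer_set(bands: BandMatrix) -> tuple[list[str], list[int]]:
    """Greedy primer subset distinguishing the most accessions.

    Repeatedly adds the primer splitting the largest number of currently
    indistinguishable accession pairs (ties broken by input primer order)
    until no primer adds discrimination. Returns the chosen primers and
    the number of distinct codes after each addition; fully identical
    accessions yield an empty set and a single code.
    """
    n = bands.n_accessions
    if n < 2:
        raise ValueError("need >= 2 accessions")
    patterns = {
        p: [tuple(bands.primer_slots(p)[i]) for i in range(n)]
        for p in bands.primer_names
    }
    chosen: list[str] = []
    counts: list[int] = []
    groups: list[list[int]] = [list(range(n))]

    def pairs_split(primer: str) -> int:
        split = 0
        for g in groups:
            if len(g) < 2:
                continue
            sub: dict[tuple, int] = {}
            for i in g:
                sub[patterns[primer][i]] = sub.get(patterns[primer][i], 0) + 1
            total = len(g) * (len(g) - 1) // 2
            same = sum(c * (c - 1) // 2 for c in sub.values())
            split += total - same
        return split

    while True:
        gains = [(pairs_split(p), p) for p in bands.primer_names if p not in chosen]
        if not gains:
            break
        best_gain = max(g for g, _ in gains)
        if best_gain == 0:
            break
        best_primer = next(p for g, p in gains if g == best_gain)
        chosen.append(best_primer)
        new_groups: list[list[int]] = []
        for g in groups:
            sub: dict[tuple, list[int]] = {}
            for i in g:
                sub.setdefault(patterns[best_primer][i], []).append(i)
            new_groups.extend(sub.values())
        groups = new_groups
        counts.append(len(groups))
    if not chosen:
        counts = [1]
    return chosen, counts


def build_id_payload(code: FingerprintCode, meta: Mapping[str, str]) -> IDPayload:
    """Molecular-ID payload text from a fingerprint code and metadata row.

    ``meta`` must provide non-empty Name, Unicode, Source and
    Classification; a missing or empty field is an error naming it. The
    payload text is byte-identical across runs for identical inputs.
    """
    vals = {}
    for f in PAYLOAD_FIELDS:
        v = str(meta.get(f, "") or "").strip()
        if not v:
            raise ValueError(f"missing metadata field {f!r} for {code.accession_id!r}")
        vals[f] = v
    return IDPayload(
        vals["Name"], vals["Unicode"], vals["Source"], vals["Classification"], code.code
    )


def parse_id_payload(text: str) -> IDPayload:
    """Inverse of :meth:`IDPayload.text`."""
    fields: dict[str, str] = {}
    for line in text.splitlines():
        key, _, val = line.partition(": ")
        fields[key] = val
    try:
        return IDPayload(
            fields["Name"], fields["Unicode"], fields["Source"],
            fields["Classification"], fields["Code"],
        )
    except KeyError as e:
        raise ValueError(f"payload missing field {e.args[0]!r}") from None
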