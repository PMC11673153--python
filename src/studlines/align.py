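"""Reference-anchored semi-global alignment and variant extraction.

A query sequence is aligned as an infix of the reference (free end gaps
on the reference, the whole query consumed) with edlib, and the
alignment path is converted into 1-based reference-coordinate variant
calls plus a coverage mask.  IUPAC ambiguity codes in the query are
treated as non-calls: the corresponding reference positions are dropped
from coverage and never produce variants.  Indels are left-aligned
against the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

ACGT = frozenset("ACGT")

# IUPAC ambiguity codes and the bases they stand for; used only to keep
# edlib from over-penalising ambiguous query positions during placement.
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_EQUALITIES = [(code, base) for code, bases in _IUPAC.items() for base in bases]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


class UnalignableSequenceError(ValueError):
    """No anchor found: best alignment exceeds the edit-distance floor."""


class InsufficientCoverageError(ValueError):
    """Aligned overlap with the region of interest is below the minimum."""


@dataclass(frozen=True)
class AlignedVariant:
    """A raw variant in reference coordinates (1-based).

    ``kind`` is ``substitution``, ``insertion`` or ``deletion``.  For an
    insertion ``position`` is the reference base immediately left of the
    inserted bases and ``ref`` is empty; for a deletion ``position`` is
    the first deleted reference base and ``alt`` is empty.
    """

    position: int
    ref: str
    alt: str
    kind: str


@dataclass(frozen=True)
class AlignmentResult:
    ref_start: int          # 1-based first reference position covered
    ref_end: int            # 1-based last reference position covered
    edit_distance: int
    variants: tuple[AlignedVariant, ...]
    coverage: frozenset[int]


def _left_align(variant: AlignedVariant, reference: str) -> AlignedVariant:
    """Shift an indel left while the flanking context permits."""
    if variant.kind == "substitution":
        return variant
    seq = variant.ref if variant.kind == "deletion" else variant.alt
    pos = variant.position
    while pos > 1:
        prev = reference[pos - 2]
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        pos -= 1
    if variant.kind == "deletion":
        return AlignedVariant(pos, seq, "", "deletion")
    return AlignedVariant(pos, "", seq, "insertion")


def semiglobal_align(
    query: str,
    reference: str,
    *,
    max_distance_fraction: float = 0.25,
) -> AlignmentResult:
    """Anchor ``query`` inside ``reference`` and extract variants.

    Raises :class:`UnalignableSequenceError` when the best placement
    needs more than ``max_distance_fraction * len(query)`` edits.
    """
    query = query.upper()
    if not query:
        raise UnalignableSequenceError("empty query")
    k = max(1, int(len(query) * max_distance_fraction))
    res = edlib.align(query, reference, mode="HW", task="path", k=k,
                      additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:
        raise UnalignableSequenceError(
            f"no placement within {k} edits for query of length {len(query)}"
        )
    ref_start0 = res["locations"][0][0]  # 0-based
    variants: list[AlignedVariant] = []
    coverage: set[int] = set()
    ri = ref_start0  # 0-based reference cursor
    qi = 0           # 0-based query cursor
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(count)
        if op == "=":
            for j in range(n):
                if query[qi + j] in ACGT:
                    coverage.add(ri + j + 1)
            ri += n
            qi += n
        elif op == "X":
            for j in range(n):
                qb = query[qi + j]
                rb = reference[ri + j]
                if qb in ACGT:
                    coverage.add(ri + j + 1)
                    if qb != rb:
                        variants.append(
                            AlignedVariant(ri + j + 1, rb, qb, "substitution")
                        )
                # ambiguity code: drop from coverage, no call
            ri += n
            qi += n
        elif op == "D":  # reference bases absent from the query
            deleted = reference[ri : ri + n]
            variants.append(_left_align(
                AlignedVariant(ri + 1, deleted, "", "deletion"), reference))
            coverage.update(range(ri + 1, ri + n + 1))
            ri += n
        elif op == "I":  # extra query bases
            inserted = query[qi : qi + n]
            if set(inserted) <= ACGT and ri > 0:
                variants.append(_left_align(
                    AlignedVariant(ri, "", inserted, "insertion"), reference))
            qi += n
    return AlignmentResult(
        ref_start=ref_start0 + 1,
        ref_end=ri,
        edit_distance=res["editDistance"],
        variants=tuple(sorted(variants, key=lambda v: (v.position, v.kind))),
        coverage=frozenset(coverage),
    )
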