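"""mtDNA control-region haplotyping.

Samples are aligned to the reference D-loop coordinate frame, variants
are called relative to it, and identical variant profiles are joined
into named haplotypes.  Because different samples cover different parts
of the control region (the downstream segment is often truncated),
haplotype identity is always evaluated over the *intersection* of
coverage: a partially covered sample consistent with exactly one
catalogued haplotype is merged into it, a sample consistent with
several is reported as an ambiguity set, and a profile consistent with
none mints a new haplotype name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from studlines.align import (
    AlignmentResult,
    InsufficientCoverageError,
    UnalignableSequenceError,
    semiglobal_align,
)
from studlines.reference import Interval, ReferenceMap

__all__ = [
    "DLoopSequence",
    "VariantCall",
    "MtHaplotype",
    "HaplogroupRule",
    "HaplotypeCatalogue",
    "HaplotypeCall",
    "HaplogroupCall",
    "anchor_align",
    "call_haplotype",
    "count_polymorphic_sites",
    "assign_haplogroup",
    "pairwise_differences",
    "BadRegionError",
    "UninformativeSampleError",
]


class BadRegionError(ValueError):
    """Requested region falls outside the D-loop interval."""


class UninformativeSampleError(ValueError):
    """Sample coverage does not overlap any catalogued haplotype."""


@dataclass(frozen=True)
class DLoopSequence:
    """One sampled control-region sequence with its pedigree metadata."""

    sample_id: str
    sequence: str
    family_label: str | None = None
    year_collected: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.sample_id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTRYSWKMBDHVN-")
        if bad:
            raise ValueError(f"{self.sample_id}: non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True, order=True)
class VariantCall:
    """A variant in 1-based reference coordinates.

    For substitutions ``ref_allele`` and ``alt_allele`` have equal
    length; insertions anchor at the reference base to their left and
    carry an empty ``ref_allele``; deletions carry an empty
    ``alt_allele`` and span ``len(ref_allele)`` reference positions.
    """

    position: int
    ref_allele: str
    alt_allele: str
    kind: str = "substitution"

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "substitution" and len(self.ref_allele) != len(self.alt_allele):
            raise ValueError("substitution alleles must have equal length")

    def span(self) -> range:
        """Reference positions the variant occupies."""
        if self.kind == "insertion":
            return range(self.position, self.position + 1)
        return range(self.position, self.position + max(1, len(self.ref_allele)))


@dataclass(frozen=True)
class MtHaplotype:
    """A named variant profile with a coverage mask.

    Positions absent from ``coverage`` are "nd" (no data): nothing is
    asserted about the sample state there and they never contribute to
    haplotype identity or site counts.
    """

    name: str
    variants: frozenset[VariantCall]
    coverage: frozenset[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for v in self.variants:
            for p in v.span():
                if p in seen:
                    raise ValueError(f"{self.name}: overlapping variants at np {p}")
                seen.add(p)

    def validate_against(self, ref: ReferenceMap) -> None:
        lo, hi = ref.dloop_interval
        for v in self.variants:
            if not (lo <= v.position <= hi):
                raise ValueError(f"{self.name}: variant at np {v.position} outside D-loop")
            if v.kind != "insertion":
                expect = ref.slice((v.position, v.position + len(v.ref_allele) - 1))
                if v.ref_allele != expect:
                    raise ValueError(
                        f"{self.name}: ref allele {v.ref_allele!r} at np {v.position} "
                        f"does not match reference {expect!r}"
                    )

    def state_at(self, position: int) -> str | None:
        """Site state: alt base, '-' inside a deletion, '.' reference-like,
        or None when the position is not covered."""
        if position not in self.coverage:
            return None
        for v in self.variants:
            if v.kind == "substitution" and position in v.span():
                return v.alt_allele[position - v.position]
            if v.kind == "deletion" and position in v.span():
                return "-"
        return "."


@dataclass(frozen=True)
class HaplogroupRule:
    """Diagnostic motif for one haplogroup; lower priority value wins first."""

    haplogroup: str
    diagnostic_motif: frozenset[VariantCall]
    priority: int

    def __post_init__(self) -> None:
        if not self.diagnostic_motif:
            raise ValueError(f"haplogroup {self.haplogroup}: empty motif")


@dataclass
class HaplotypeCatalogue:
    """Ordered collection of named haplotypes with a minting convention.

    ``suffix`` is appended to newly minted names to mark them as local
    to the stud under analysis.
    """

    haplotypes: dict[str, MtHaplotype] = field(default_factory=dict)
    new_name_prefix: str = "HT"
    suffix: str = ""
    _minted: int = 0

    @classmethod
    def from_list(cls, haps: list[MtHaplotype], **kwargs) -> "HaplotypeCatalogue":
        cat = cls(**kwargs)
        for h in haps:
            cat.add(h)
        return cat

    def add(self, hap: MtHaplotype) -> None:
        if hap.name in self.haplotypes:
            raise ValueError(f"duplicate haplotype name {hap.name}")
        self.haplotypes[hap.name] = hap

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes.values())

    def names(self) -> list[str]:
        return list(self.haplotypes)

    def mint_name(self) -> str:
        self._minted += 1
        return f"{self.new_name_prefix}{len(self.haplotypes) + 1:02d}{self.suffix}"


@dataclass(frozen=True)
class HaplotypeCall:
    """Outcome of matching one sample against a catalogue."""

    name: str
    matches: tuple[str, ...]   # catalogued names consistent with the sample
    minted: bool

    @property
    def ambiguous(self) -> bool:
        return len(self.matches) > 1


def anchor_align(
    seq: DLoopSequence | str,
    ref: ReferenceMap,
    *,
    max_distance_fraction: float = 0.25,
    min_overlap: int = 200,
) -> tuple[AlignmentResult, list[VariantCall]]:
    """Align a sample to the reference frame and call D-loop variants.

    The query is placed semi-globally (free end gaps on the reference),
    variants are reported in 1-based reference coordinates with indels
    left-aligned, and positions inside the repeat array are excluded
    from both the variant list and the coverage mask.

    Raises
    ------
    UnalignableSequenceError
        No placement within the edit-distance floor.
    InsufficientCoverageError
        Aligned overlap with the D-loop shorter than ``min_overlap``.
    """
    query = seq.sequence if isinstance(seq, DLoopSequence) else seq
    res = semiglobal_align(query, ref.sequence, max_distance_fraction=max_distance_fraction)
    dloop = ref.dloop_positions()
    masked = ref.repeat_positions()
    coverage = frozenset((res.coverage & dloop) - masked)
    if len(coverage) < min_overlap:
        raise InsufficientCoverageError(
            f"only {len(coverage)} D-loop positions covered (< {min_overlap})"
        )
    variants = []
    for v in res.variants:
        span = set(range(v.position, v.position + max(1, len(v.ref))))
        if span & masked or not span <= dloop:
            continue
        variants.append(VariantCall(v.position, v.ref, v.alt, v.kind))
    trimmed = AlignmentResult(
        ref_start=res.ref_start,
        ref_end=res.ref_end,
        edit_distance=res.edit_distance,
        variants=res.variants,
        coverage=coverage,
    )
    return trimmed, sorted(variants)


def _profile(variants, positions: frozenset[int]) -> frozenset[VariantCall]:
    """Variants whose footprint lies entirely inside ``positions``."""
    return frozenset(v for v in variants if set(v.span()) <= positions)


def call_haplotype(
    variants,
    coverage: frozenset[int],
    catalogue: HaplotypeCatalogue,
    *,
    mint: bool = True,
) -> HaplotypeCall:
    """Match a variant profile against the catalogue over shared coverage.

    A sample matches a catalogued haplotype iff, restricted to positions
    covered in both, the two variant sets are identical.  Several
    matches (possible with coverage gaps) yield an ambiguity set whose
    first name is reported; no match mints a new name (added to the
    catalogue when ``mint`` is true).

    Raises :class:`UninformativeSampleError` when a non-empty catalogue
    shares no covered position with the sample.
    """
    variants = frozenset(variants)
    matches = []
    informative = len(catalogue) == 0
    for hap in catalogue:
        common = coverage & hap.coverage
        if not common:
            continue
        informative = True
        if _profile(variants, common) == _profile(hap.variants, common):
            matches.append(hap.name)
    if not informative:
        raise UninformativeSampleError("no coverage overlap with any catalogued haplotype")
    if len(matches) == 1:
        return HaplotypeCall(matches[0], (matches[0],), minted=False)
    if len(matches) > 1:
        ordered = tuple(n for n in catalogue.names() if n in matches)
        return HaplotypeCall(ordered[0], ordered, minted=False)
    name = catalogue.mint_name()
    if mint:
        catalogue.add(MtHaplotype(name, variants, coverage))
    return HaplotypeCall(name, (), minted=True)


def count_polymorphic_sites(
    haps,
    region: Interval,
    mode: str = "among-haplotypes",
    *,
    ref: ReferenceMap | None = None,
) -> int:
    """Number of polymorphic sites in ``region`` among haplotypes.

    In ``among-haplotypes`` mode a position counts iff at least two
    distinct states are observed among the haplotypes covering it
    (positions covered by fewer than two haplotypes are skipped); in
    ``vs-reference`` mode, iff any covering haplotype differs from the
    reference.  Insertions do not occupy a reference position and never
    contribute a site.
    """
    haps = list(haps)
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes")
    if mode not in ("among-haplotypes", "vs-reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if ref is not None:
        lo, hi = ref.dloop_interval
        if not (lo <= region[0] <= region[1] <= hi):
            raise BadRegionError(f"region {region} outside D-loop ({lo}, {hi})")
    count = 0
    for pos in range(region[0], region[1] + 1):
        states = [s for s in (h.state_at(pos) for h in haps) if s is not None]
        if mode == "among-haplotypes":
            if len(states) >= 2 and len(set(states)) >= 2:
                count += 1
        else:
            if any(s != "." for s in states):
                count += 1
    return count


@dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str          # single letter, or "unclassified"
    rule_priority: int | None
    uncovered_rules: tuple[str, ...]   # rules skipped because a motif position was "nd"


def assign_haplogroup(hap: MtHaplotype, rules) -> HaplogroupCall:
    """Classify a haplotype by the highest-priority fully matching motif.

    A rule matches when every motif variant is present in the haplotype
    and every motif position is covered.  A rule whose motif variants
    are otherwise consistent but fall on uncovered positions is treated
    as a non-match and flagged in ``uncovered_rules``.
    """
    rules = sorted(rules, key=lambda r: r.priority)
    if len({r.priority for r in rules}) != len(rules):
        raise ValueError("rule priorities must be unique")
    uncovered: list[str] = []
    for rule in rules:
        positions = {p for v in rule.diagnostic_motif for p in v.span()}
        if not positions <= hap.coverage:
            uncovered.append(rule.haplogroup)
            continue
        if rule.diagnostic_motif <= hap.variants:
            return HaplogroupCall(rule.haplogroup, rule.priority, tuple(uncovered))
    return HaplogroupCall("unclassified", None, tuple(uncovered))


def pairwise_differences(haps) -> pd.DataFrame:
    """Symmetric matrix of per-site differences over shared coverage.

    The distance between two haplotypes is the number of reference
    positions covered in both at which their site states differ.  This
    is the plain mismatch count a distance-based summary of haplotype
    divergence needs; no evolutionary correction is applied.
    """
    haps = list(haps)
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes")
    names = [h.name for h in haps]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(haps):
        for b in haps[i + 1 :]:
            shared = a.coverage & b.coverage
            interesting = {p for v in (a.variants | b.variants) for p in v.span()}
            d = sum(
                1
                for p in interesting & shared
                if a.state_at(p) != b.state_at(p)
            )
            mat.loc[a.name, b.name] = d
            mat.loc[b.name, a.name] = d
    return mat
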