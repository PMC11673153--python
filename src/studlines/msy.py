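"""Male-specific Y-chromosome (MSY) haplotype typing.

Stallions are typed at three polymorphic loci (YE3, YE17, YXX), each
with its own reference sequence and one diagnostic position.  The
haplotype rule table maps per-locus states to the European MSY
haplotypes: the YE17 np-1277 variant defines HT02 (the
Neapolitan/Oriental wave); a variant at the configured third-locus
position defines HT3 (the Thoroughbred wave); all-reference stallions
carry the ancestral HT01.  Which of YE3/YXX defines HT3 is
configuration: the packaged default uses YXX, and analyses of real data
should set the rule table explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from studlines.align import semiglobal_align

__all__ = [
    "MsyLocus",
    "MsyGenotype",
    "MsyHaplotypeRule",
    "DEFAULT_MSY_RULES",
    "LocusCall",
    "synthetic_msy_loci",
    "type_locus",
    "call_msy",
    "msy_frequencies",
    "UncallableGenotypeError",
]

LOCI = ("YE3", "YE17", "YXX")


class UncallableGenotypeError(ValueError):
    """All loci missing; no haplotype can be called."""


@dataclass(frozen=True)
class MsyLocus:
    """One MSY amplicon: reference sequence plus its diagnostic position."""

    name: str
    reference_id: str
    sequence: str
    diagnostic_position: int  # 1-based on the locus reference

    def __post_init__(self) -> None:
        if not (1 <= self.diagnostic_position <= len(self.sequence)):
            raise ValueError(
                f"{self.name}: diagnostic position {self.diagnostic_position} "
                f"outside reference of length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MsyGenotype:
    """Per-locus states for one stallion: reference | variant | missing."""

    sample_id: str
    states: dict[str, str]  # locus name -> state

    def __post_init__(self) -> None:
        for locus, state in self.states.items():
            if state not in ("reference", "variant", "missing"):
                raise ValueError(f"{self.sample_id}/{locus}: bad state {state!r}")

    @property
    def callable(self) -> bool:
        return any(s != "missing" for s in self.states.values())


@dataclass(frozen=True)
class MsyHaplotypeRule:
    """Haplotype defined by a variant state at one locus."""

    haplotype: str
    locus: str  # locus whose variant state defines the haplotype


#: Default rule table: YE17 variant -> HT02, YXX variant -> HT3,
#: all observed loci reference -> HT01.
DEFAULT_MSY_RULES = (
    MsyHaplotypeRule("HT02", "YE17"),
    MsyHaplotypeRule("HT3", "YXX"),
)

_LOCUS_FRAME_SEEDS = {"YE3": 646942, "YE17": 646950, "YXX": 647030}
_DIAGNOSTIC_POSITIONS = {"YE3": 171, "YE17": 1277, "YXX": 204}
_LOCUS_LENGTHS = {"YE3": 400, "YE17": 1500, "YXX": 450}


def synthetic_msy_loci() -> dict[str, MsyLocus]:
    """Deterministic synthetic locus references.

    The published amplicon references cannot be redistributed, so the
    packaged loci are synthetic stand-ins that preserve the analysis
    contract: a fixed sequence per locus and the documented diagnostic
    position (YE17 uses its published np 1277; the YE3/YXX positions
    are package defaults).
    """
    loci = {}
    bases = np.array(list("ACGT"))
    for name in LOCI:
        rng = np.random.default_rng(_LOCUS_FRAME_SEEDS[name])
        seq = "".join(rng.choice(bases, size=_LOCUS_LENGTHS[name]))
        loci[name] = MsyLocus(
            name=name,
            reference_id=f"SYNTH_{name}_FRAME",
            sequence=seq,
            diagnostic_position=_DIAGNOSTIC_POSITIONS[name],
        )
    return loci


@dataclass(frozen=True)
class LocusCall:
    locus: str
    state: str                                   # reference | variant | missing
    non_diagnostic_variants: tuple = ()          # logged, never used for typing


def type_locus(
    sequence: str,
    locus: MsyLocus,
    *,
    max_distance_fraction: float = 0.25,
) -> LocusCall:
    """State at the locus' diagnostic position for one sequence.

    The sequence is anchored semi-globally on the locus reference; the
    call is the state at the diagnostic position, with any other
    observed variants logged as non-diagnostic.  An alignment that does
    not cover the diagnostic position yields ``missing``.
    """
    res = semiglobal_align(
        sequence, locus.sequence, max_distance_fraction=max_distance_fraction
    )
    pos = locus.diagnostic_position
    diagnostic = [v for v in res.variants if pos in range(v.position, v.position + max(1, len(v.ref)))]
    others = tuple(v for v in res.variants if v not in diagnostic)
    if pos not in res.coverage:
        return LocusCall(locus.name, "missing", others)
    state = "variant" if diagnostic else "reference"
    return LocusCall(locus.name, state, others)


def call_msy(genotype: MsyGenotype, rules=DEFAULT_MSY_RULES) -> str:
    """Apply the haplotype rule table to one genotype.

    Exactly one rule locus in the variant state selects that rule's
    haplotype; no variant at any observed locus yields HT01; variants
    at several rule loci, or a variant at a locus no rule covers, yield
    ``unclassified``.  All-missing genotypes raise
    :class:`UncallableGenotypeError`.
    """
    if not genotype.callable:
        raise UncallableGenotypeError(genotype.sample_id)
    rule_loci = {r.locus for r in rules}
    if len(rule_loci) != len(rules):
        raise ValueError("rule-defining loci must be mutually exclusive")
    variant_loci = [l for l, s in genotype.states.items() if s == "variant"]
    if not variant_loci:
        return "HT01"
    if len(variant_loci) == 1 and variant_loci[0] in rule_loci:
        (rule,) = [r for r in rules if r.locus == variant_loci[0]]
        return rule.haplotype
    return "unclassified"


def msy_frequencies(calls) -> pd.DataFrame:
    """Counts and percentages per haplotype over callable stallions.

    ``calls`` is an iterable of haplotype labels (use ``None`` for
    uncallable stallions; they are reported in a separate row and
    excluded from the percentage denominator).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls")
    callable_calls = [c for c in calls if c is not None]
    n = len(callable_calls)
    counts = pd.Series(callable_calls).value_counts()
    rows = [
        {"haplotype": h, "count": int(c), "percent": round(100.0 * c / n, 1)}
        for h, c in counts.items()
    ]
    if len(callable_calls) < len(calls):
        rows.append(
            {"haplotype": "uncallable", "count": len(calls) - n, "percent": float("nan")}
        )
    return pd.DataFrame(rows, columns=["haplotype", "count", "percent"])
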