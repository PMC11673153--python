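"""Packaged study fixtures: motif catalogue, stud table, rule sets.

The haplotype motif catalogue here is *synthetic*: the deposited
haplotype sequences cannot be shipped with the package, so the ten
catalogued haplotypes are built as substitution motifs on the synthetic
reference frame, shaped to the published summary structure of the real
data — 55 polymorphic sites in the UP segment and 8 in DOWN among the
ten haplotypes, shared-motif groups mirroring the reported haplotype
clusters, and four or more private sites per haplotype so that every
profile is unique.  Analyses of real sequences should load the real
reference and catalogue instead.

The 2014 stud table (93 mares across 11 maternal families and 10
haplotypes) is transcribed as counts and expanded into deterministic
per-mare records; it is the single source for every worked example
anchored on that census.
"""

from __future__ import annotations

from studlines.mito import HaplogroupRule, HaplotypeCatalogue, MtHaplotype, VariantCall
from studlines.msy import MsyGenotype
from studlines.reference import ReferenceMap, synthetic_dloop_reference

__all__ = [
    "FAMILY_NAMES",
    "HAPLOTYPE_SHORT_NAMES",
    "STUD_SUFFIX",
    "FAMILY_HAPLOTYPE_MAP",
    "TABLE_2014",
    "full_name",
    "build_motif_catalogue",
    "distinct_family_catalogue",
    "default_haplogroup_rules",
    "table1_records",
    "ascal_stallions",
]

#: The 11 classical maternal families kept in the stud.
FAMILY_NAMES = (
    "Africa",
    "Almerina",
    "Argentina",
    "Deflorata",
    "Djebrin",
    "Europa",
    "Fistula",
    "Ivanka",
    "Sardinia",
    "Spadiglia",
    "Theodorosta",
)

#: Haplotype short names in census-table column order.
HAPLOTYPE_SHORT_NAMES = (
    "X",
    "Capriola",
    "Allegra",
    "Monteaura",
    "U",
    "Dubovina",
    "Batosta",
    "J",
    "Slavina",
    "Wera",
)

STUD_SUFFIX = "_ASCAL_ITA"


def full_name(short: str) -> str:
    return f"{short}{STUD_SUFFIX}"


#: Family -> haplotype truth map (Europa and Theodorosta share "U").
FAMILY_HAPLOTYPE_MAP = {
    "Africa": full_name("Batosta"),
    "Almerina": full_name("Slavina"),
    "Argentina": full_name("X"),
    "Deflorata": full_name("Capriola"),
    "Djebrin": full_name("Dubovina"),
    "Europa": full_name("U"),
    "Fistula": full_name("Allegra"),
    "Ivanka": full_name("J"),
    "Sardinia": full_name("Wera"),
    "Spadiglia": full_name("Monteaura"),
    "Theodorosta": full_name("U"),
}

#: The 2014 census: mares per (family, haplotype) combination.
TABLE_2014 = {
    "Africa": {"Monteaura": 2, "Batosta": 7},
    "Almerina": {"Capriola": 4, "Allegra": 3, "Slavina": 2},
    "Argentina": {"X": 5, "Capriola": 4, "U": 3, "J": 1},
    "Deflorata": {"Capriola": 6, "Allegra": 2},
    "Djebrin": {"Dubovina": 9},
    "Europa": {"U": 1},
    "Fistula": {"Capriola": 6, "Allegra": 5},
    "Ivanka": {"J": 15},
    "Sardinia": {"Capriola": 3, "Monteaura": 7, "Wera": 2},
    "Spadiglia": {"X": 3, "Monteaura": 2},
    "Theodorosta": {"U": 1},
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# UP-segment site layout (all below the repeat array at np 16129).
# 4 private sites per haplotype, then shared blocks mirroring the
# reported haplotype clusters.
_PRIVATE_BASE = 15460
_PRIVATE_STEP = 12
_SHARED_SITES = {
    # C1-like cluster
    ("X", "Capriola", "Dubovina", "Batosta", "Slavina"): (15950, 15962, 15974, 15986, 15998),
    # C4-like cluster (haplogroup L)
    ("Allegra", "Wera", "Monteaura"): (16010, 16022, 16034, 16046, 16058),
    # haplogroup G subgroup
    ("X", "Dubovina", "Slavina"): (16070, 16082),
    # Asian-origin pair
    ("U", "J"): (16094, 16102, 16110),
}
# DOWN-segment sites: groups identical in DOWN share them.
_DOWN_SITES = {
    ("Allegra", "Wera"): (16170, 16182),
    ("Capriola", "Slavina", "Dubovina", "X"): (16200, 16212, 16224),
    ("J",): (16240,),
    ("U",): (16252,),
    ("Batosta",): (16264,),
}


def _private_sites(index: int) -> tuple[int, ...]:
    return tuple(
        _PRIVATE_BASE + _PRIVATE_STEP * (4 * index + j) for j in range(4)
    )


def _motif_positions() -> dict[str, list[int]]:
    sites: dict[str, list[int]] = {s: [] for s in HAPLOTYPE_SHORT_NAMES}
    for i, short in enumerate(HAPLOTYPE_SHORT_NAMES):
        sites[short].extend(_private_sites(i))
    for group, positions in {**_SHARED_SITES, **_DOWN_SITES}.items():
        for short in group:
            sites[short].extend(positions)
    return sites


def _haplotype(short: str, positions, ref: ReferenceMap) -> MtHaplotype:
    coverage = frozenset(ref.dloop_positions() - ref.repeat_positions())
    variants = frozenset(
        VariantCall(p, ref.base(p), _TRANSITION[ref.base(p)]) for p in positions
    )
    return MtHaplotype(full_name(short), variants, coverage)


def build_motif_catalogue(ref: ReferenceMap | None = None) -> HaplotypeCatalogue:
    """The packaged ten-haplotype synthetic motif catalogue."""
    ref = ref or synthetic_dloop_reference()
    sites = _motif_positions()
    haps = [_haplotype(s, sites[s], ref) for s in HAPLOTYPE_SHORT_NAMES]
    return HaplotypeCatalogue.from_list(haps, suffix=STUD_SUFFIX)


def distinct_family_catalogue(ref: ReferenceMap | None = None) -> tuple[HaplotypeCatalogue, dict[str, str]]:
    """Eleven-haplotype variant of the catalogue with one motif per family.

    Splits the shared Europa/Theodorosta haplotype by giving Theodorosta
    a private synthetic motif, so that every recording error between
    families is detectable.  Returns (catalogue, family -> haplotype map).
    """
    ref = ref or synthetic_dloop_reference()
    cat = build_motif_catalogue(ref)
    theo = _haplotype("Theo", (15932, 15936, 15940, 15944), ref)
    cat.add(theo)
    fam_map = dict(FAMILY_HAPLOTYPE_MAP)
    fam_map["Theodorosta"] = theo.name
    return cat, fam_map


def default_haplogroup_rules(ref: ReferenceMap | None = None) -> list[HaplogroupRule]:
    """Synthetic example haplogroup rules for the packaged catalogue.

    Real haplogroup nomenclature motifs are not redistributable here;
    these rules key on catalogue motif sites so that the packaged
    haplotypes classify into the six published haplogroups
    (G and L with three haplotypes each; B, C, M, Q with one).
    """
    ref = ref or synthetic_dloop_reference()

    def motif(positions):
        return frozenset(
            VariantCall(p, ref.base(p), _TRANSITION[ref.base(p)]) for p in positions
        )

    sites = _motif_positions()
    return [
        HaplogroupRule("G", motif((16070, 16082)), priority=1),
        HaplogroupRule("L", motif((16010, 16022)), priority=2),
        HaplogroupRule("Q", motif(sites["J"][:1]), priority=3),
        HaplogroupRule("M", motif(sites["U"][:1]), priority=4),
        HaplogroupRule("B", motif(sites["Capriola"][:1]), priority=5),
        HaplogroupRule("C", motif(sites["Batosta"][:1]), priority=6),
    ]


def table1_records() -> list[tuple[str, str, str]]:
    """The 93 mare records of the 2014 census as
    (sample_id, family, haplotype) triples, in deterministic order."""
    records = []
    n = 0
    for family in FAMILY_NAMES:
        for short in HAPLOTYPE_SHORT_NAMES:
            for _ in range(TABLE_2014[family].get(short, 0)):
                n += 1
                records.append((f"M2014_{n:03d}", family, full_name(short)))
    return records


def ascal_stallions() -> list[MsyGenotype]:
    """The stallion MSY fixture: eight carriers of the YE17 np-1277
    variant and two all-reference stallions.

    The total of ten is implied by the published modal frequency (80%)
    together with the eight observed variant carriers.
    """
    genotypes = []
    for i in range(1, 9):
        genotypes.append(
            MsyGenotype(f"ST{i:02d}", {"YE3": "reference", "YE17": "variant", "YXX": "reference"})
        )
    for i in range(9, 11):
        genotypes.append(
            MsyGenotype(f"ST{i:02d}", {"YE3": "reference", "YE17": "reference", "YXX": "reference"})
        )
    return genotypes
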