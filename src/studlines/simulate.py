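"""Synthetic closed-stud generator.

Emulates the data-generating process the analysis assumes: a closed
multi-generation pedigree with a fixed set of maternal families, strict
dam-to-offspring mtDNA transmission, and clerical noise in the form of
a configurable family-label recording-error rate.  A recording error
swaps only the *recorded* family label of a mare, never her transmitted
haplotype — discordance between haplotype and label therefore always
indicates a pedigree error, which is exactly the signal the analysis
looks for.

All randomness flows through one ``numpy`` generator seeded from the
scenario, so runs are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from studlines.fixtures import (
    FAMILY_HAPLOTYPE_MAP,
    FAMILY_NAMES,
    build_motif_catalogue,
    table1_records,
)
from studlines.mito import HaplotypeCatalogue
from studlines.msy import LOCI, MsyGenotype, MsyLocus
from studlines.pedigree import Pedigree, PedigreeRecord
from studlines.reference import Interval, ReferenceMap, synthetic_dloop_reference

__all__ = [
    "StudScenario",
    "StudSimulation",
    "MatrilineExtinctionError",
    "simulate_stud",
    "emit_sequences",
    "emit_msy",
    "emit_msy_sequences",
    "table1_records",
]


class MatrilineExtinctionError(RuntimeError):
    """A maternal family died out in every bounded retry."""


@dataclass(frozen=True)
class StudScenario:
    """Parameters of one synthetic closed stud.

    Defaults describe a stud like the one the package targets: 11
    maternal families, a handful of foundress mares per family, within-
    stud mating over several generations, and error-free recording
    unless ``label_error_rate`` is raised.
    """

    family_names: tuple[str, ...] = FAMILY_NAMES
    founders_per_family: int = 4
    male_founders: int = 6
    generations: int = 5
    offspring_mean: float = 3.0
    label_error_rate: float = 0.0
    missing_sire_rate: float = 0.0
    family_haplotypes: dict[str, str] = field(
        default_factory=lambda: dict(FAMILY_HAPLOTYPE_MAP)
    )
    msy_proportions: dict[str, float] = field(
        default_factory=lambda: {"HT02": 0.8, "HT01": 0.2}
    )
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_error_rate <= 1.0:
            raise ValueError("label_error_rate must be in [0, 1]")
        if abs(sum(self.msy_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("msy_proportions must sum to 1")
        missing = set(self.family_names) - set(self.family_haplotypes)
        if missing:
            raise ValueError(f"families without a haplotype motif: {sorted(missing)}")


@dataclass
class StudSimulation:
    """A simulated stud plus its ground truth."""

    scenario: StudScenario
    pedigree: Pedigree
    true_family: dict[str, str]      # matriline founder family per individual
    recorded_family: dict[str, str]  # per female, possibly error-injected
    haplotype: dict[str, str]        # transmitted mtDNA haplotype name
    error_log: list[dict]            # one entry per injected label error
    missing_sire_ids: list[str]
    founder_haplotypes: dict[str, str]  # dam-line founder id -> haplotype

    @property
    def mares(self) -> list[str]:
        return [i for i, r in self.pedigree.records.items() if r.sex == "F"]

    def mare_table(self) -> pd.DataFrame:
        """Recorded family and true haplotype per mare (the table a
        sequencing campaign plus studbook lookup would produce)."""
        rows = [
            {
                "sample_id": i,
                "family": self.recorded_family[i],
                "haplotype": self.haplotype[i],
            }
            for i in self.mares
        ]
        return pd.DataFrame(rows, columns=["sample_id", "family", "haplotype"])


def _simulate_once(scenario: StudScenario, rng: np.random.Generator):
    records: list[PedigreeRecord] = []
    true_family: dict[str, str] = {}
    haplotype: dict[str, str] = {}
    missing_sires: list[str] = []
    founder_haps: dict[str, str] = {}
    base_year = 1980

    females: list[str] = []
    males: list[str] = []
    for family in scenario.family_names:
        for j in range(scenario.founders_per_family):
            ind = f"F0_{family[:3].upper()}{j:02d}"
            records.append(PedigreeRecord(ind, None, None, "F", base_year, family))
            true_family[ind] = family
            haplotype[ind] = scenario.family_haplotypes[family]
            founder_haps[ind] = haplotype[ind]
            females.append(ind)
    for j in range(scenario.male_founders):
        ind = f"F0_SIRE{j:02d}"
        records.append(PedigreeRecord(ind, None, None, "M", base_year, None))
        males.append(ind)

    counter = 0
    for gen in range(1, scenario.generations + 1):
        year = base_year + 5 * gen
        sires = males if males else [None]
        next_f: list[str] = []
        next_m: list[str] = []
        for dam in females:
            n_off = rng.poisson(scenario.offspring_mean)
            for _ in range(n_off):
                counter += 1
                ind = f"G{gen}_{counter:05d}"
                sire = sires[rng.integers(0, len(sires))]
                recorded_sire = sire
                if sire is not None and rng.random() < scenario.missing_sire_rate:
                    recorded_sire = None
                    missing_sires.append(ind)
                sex = "F" if rng.random() < 0.5 else "M"
                fam = true_family[dam]
                records.append(
                    PedigreeRecord(ind, recorded_sire, dam, sex, year, fam)
                )
                true_family[ind] = fam
                haplotype[ind] = haplotype[dam]
                (next_f if sex == "F" else next_m).append(ind)
        females, males = next_f, next_m
        if not females:
            break

    surviving = {true_family[i] for i in females}
    if surviving != set(scenario.family_names):
        return None
    return records, true_family, haplotype, missing_sires, founder_haps


def simulate_stud(scenario: StudScenario) -> StudSimulation:
    """Generate one closed stud; retries (bounded) if a maternal family
    goes extinct before the final generation."""
    rng = np.random.default_rng(scenario.seed)
    out = None
    for attempt in range(scenario.max_retries):
        out = _simulate_once(scenario, rng)
        if out is not None:
            if attempt:
                warnings.warn(
                    f"matriline extinction; succeeded on retry {attempt}",
                    stacklevel=2,
                )
            break
    if out is None:
        raise MatrilineExtinctionError(
            f"a maternal family went extinct in all {scenario.max_retries} attempts"
        )
    records, true_family, haplotype, missing_sires, founder_haps = out
    pedigree = Pedigree(records)

    recorded: dict[str, str] = {}
    error_log: list[dict] = []
    families = list(scenario.family_names)
    for rec in records:
        if rec.sex != "F":
            continue
        fam = true_family[rec.id]
        if scenario.label_error_rate > 0 and rng.random() < scenario.label_error_rate:
            others = [f for f in families if f != fam]
            wrong = others[rng.integers(0, len(others))]
            recorded[rec.id] = wrong
            error_log.append(
                {"sample_id": rec.id, "true_family": fam, "recorded_family": wrong}
            )
        else:
            recorded[rec.id] = fam
    return StudSimulation(
        scenario=scenario,
        pedigree=pedigree,
        true_family=true_family,
        recorded_family=recorded,
        haplotype=haplotype,
        error_log=error_log,
        missing_sire_ids=missing_sires,
        founder_haplotypes=founder_haps,
    )


def emit_sequences(
    samples,
    catalogue: HaplotypeCatalogue | None = None,
    ref: ReferenceMap | None = None,
    *,
    coverage_gap: Interval | None = None,
) -> list[SeqRecord]:
    """Render D-loop FASTA records for (sample_id, haplotype_name) pairs.

    Each sequence is the reference D-loop with the haplotype's
    substitution motif applied.  ``coverage_gap`` masks a 1-based
    inclusive window with ``N`` to imitate the "nd" windows real
    truncated reads leave.
    """
    ref = ref or synthetic_dloop_reference()
    catalogue = catalogue or build_motif_catalogue(ref)
    lo, hi = ref.dloop_interval
    out = []
    for sample_id, hap_name in samples:
        hap = catalogue.haplotypes[hap_name]
        seq = list(ref.slice(ref.dloop_interval))
        for v in hap.variants:
            if v.kind != "substitution":
                raise ValueError(f"{hap_name}: emitter supports substitution motifs only")
            if not (lo <= v.position <= hi):
                raise ValueError(f"{hap_name}: motif at np {v.position} outside the D-loop")
            seq[v.position - lo] = v.alt_allele
        if coverage_gap is not None:
            a, b = coverage_gap
            for p in range(max(a, lo), min(b, hi) + 1):
                seq[p - lo] = "N"
        out.append(
            SeqRecord(
                Seq("".join(seq)),
                id=sample_id,
                description=f"dloop np {lo}-{hi} haplotype={hap_name}",
            )
        )
    return out


def emit_msy(
    proportions: dict[str, float],
    n: int,
    *,
    seed: int,
) -> pd.DataFrame:
    """Stallion genotype table drawn by exact quota from haplotype
    proportions (largest-remainder apportionment), order shuffled by
    ``seed``.  Columns: sample_id, YE3, YE17, YXX."""
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    quotas = {h: p * n for h, p in proportions.items()}
    counts = {h: int(q) for h, q in quotas.items()}
    short = n - sum(counts.values())
    for h in sorted(quotas, key=lambda h: (quotas[h] - counts[h]), reverse=True)[:short]:
        counts[h] += 1
    labels = [h for h, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    state_for = {
        "HT01": {"YE3": "reference", "YE17": "reference", "YXX": "reference"},
        "HT02": {"YE3": "reference", "YE17": "variant", "YXX": "reference"},
        "HT3": {"YE3": "reference", "YE17": "reference", "YXX": "variant"},
    }
    rows = []
    for i, label in enumerate(labels, start=1):
        row = {"sample_id": f"SIM_ST{i:03d}", "true_haplotype": label}
        row.update(state_for[label])
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *LOCI, "true_haplotype"])


def emit_msy_sequences(genotype: MsyGenotype, loci: dict[str, MsyLocus]) -> dict[str, str]:
    """Per-locus sequences for one stallion genotype, with the
    diagnostic substitution planted where the state is ``variant``."""
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = {}
    for name, locus in loci.items():
        state = genotype.states.get(name, "missing")
        if state == "missing":
            continue
        seq = list(locus.sequence)
        if state == "variant":
            pos = locus.diagnostic_position
            seq[pos - 1] = transition[seq[pos - 1]]
        out[name] = "".join(seq)
    return out


def continue_breeding(
    sim: StudSimulation,
    keep_dams,
    generations: int,
    *,
    seed: int,
) -> tuple[Pedigree, dict[str, str], dict[str, str]]:
    """Breed further generations from a restricted set of dams.

    Used to study how culling decisions propagate: only ``keep_dams``
    (ids of current females) produce offspring, sires are drawn from
    the stud's current males, and mtDNA follows the dam line as usual.
    Returns the extended pedigree plus updated haplotype and
    true-family maps.
    """
    rng = np.random.default_rng(seed)
    scenario = sim.scenario
    records = list(sim.pedigree.records.values())
    true_family = dict(sim.true_family)
    haplotype = dict(sim.haplotype)
    last_year = max(r.birth_year or 0 for r in records)
    females = [i for i in keep_dams if sim.pedigree.records[i].sex == "F"]
    if not females:
        raise ValueError("no dams to breed from")
    by_year = max(
        (r.birth_year or 0) for r in records if r.sex == "M"
    )
    males = [
        r.id for r in records if r.sex == "M" and (r.birth_year or 0) == by_year
    ]
    counter = 0
    for gen in range(1, generations + 1):
        year = last_year + 5 * gen
        next_f: list[str] = []
        next_m: list[str] = []
        for dam in females:
            for _ in range(rng.poisson(scenario.offspring_mean)):
                counter += 1
                ind = f"C{gen}_{counter:05d}"
                sire = males[rng.integers(0, len(males))]
                sex = "F" if rng.random() < 0.5 else "M"
                fam = true_family[dam]
                records.append(PedigreeRecord(ind, sire, dam, sex, year, fam))
                true_family[ind] = fam
                haplotype[ind] = haplotype[dam]
                (next_f if sex == "F" else next_m).append(ind)
        if not next_f or not next_m:
            break
        females, males = next_f, next_m
    return Pedigree(records), haplotype, true_family
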