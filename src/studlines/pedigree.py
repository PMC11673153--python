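"""Pedigree-based diversity statistics for a closed population.

Implements the classical probability-of-gene-origin toolkit used to
monitor small managed populations:

* inbreeding coefficients ``F`` by recursive kinship (Malecot
  coancestry; ``F_i`` is the kinship of the parents, i.e. half the
  additive relationship between them);
* expected founder contributions ``q_k`` and equivalent founders
  ``f_e = 1 / sum(q_k^2)``;
* marginal ancestor contributions ``p_j`` (iterative selection of the
  ancestor explaining the largest not-yet-explained share of the
  reference gene pool) and effective ancestors ``f_a = 1 / sum(p_j^2)``;
* founder genome equivalents ``N_g`` estimated by gene dropping:
  every founder carries two uniquely labelled alleles, transmission is
  Mendelian, and ``N_g = 1 / (2 * E[sum_a p_a^2])`` over the reference
  population;
* pedigree completeness and strict dam-line (matriline) tracing.

The *reference population* defaults to individuals with no recorded
progeny — the current, non-reproducing tip of the pedigree.  An
individual with exactly one known parent has the unknown side routed
to a phantom founder unique to that individual, which keeps the founder
contributions summing to one.  On every valid pedigree the statistics
obey ``N_g <= f_a <= f_e <= number of founders`` (phantoms included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "PedigreeValidationError",
    "PedigreeCycleError",
    "GeneDropResult",
    "GeneOriginResult",
    "inbreeding_coefficients",
    "founder_contributions",
    "effective_ancestors",
    "founder_genomes",
    "completeness",
    "matriline_expected_haplotype",
    "gene_origin_summary",
]


class PedigreeValidationError(ValueError):
    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


class PedigreeCycleError(PedigreeValidationError):
    pass


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str | None = None          # "M" | "F" | None
    birth_year: int | None = None
    family: str | None = None       # recorded maternal family label


class Pedigree:
    """Validated pedigree graph with topological ordering helpers."""

    def __init__(self, records, *, strict: bool = True):
        self.records: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise PedigreeValidationError([f"duplicate id {rec.id}"])
            self.records[rec.id] = rec
        self._graph = nx.DiGraph()  # parent -> child
        self._graph.add_nodes_from(self.records)
        for rec in self.records.values():
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent in self.records:
                    self._graph.add_edge(parent, rec.id)
        issues = self.validate()
        if strict and issues:
            raise PedigreeValidationError(issues)
        self.issues = issues
        self._order = list(nx.topological_sort(self._graph))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, strict: bool = True) -> "Pedigree":
        """Build from a DataFrame with columns id, sire, dam, sex,
        birth_year, family; empty string or NaN means unknown."""

        def clean(v):
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return str(v)

        records = []
        for _, row in df.iterrows():
            year = row.get("birth_year")
            year = None if year is None or (isinstance(year, float) and math.isnan(year)) else int(year)
            records.append(
                PedigreeRecord(
                    id=str(row["id"]),
                    sire=clean(row.get("sire")),
                    dam=clean(row.get("dam")),
                    sex=clean(row.get("sex")),
                    birth_year=year,
                    family=clean(row.get("family")),
                )
            )
        return cls(records, strict=strict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "sire": r.sire or "",
                "dam": r.dam or "",
                "sex": r.sex or "",
                "birth_year": r.birth_year if r.birth_year is not None else "",
                "family": r.family or "",
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year", "family"])

    def validate(self) -> list[str]:
        """Cycles (hard error), dangling parents, sex conflicts and
        birth-year inversions."""
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeCycleError([f"pedigree cycle: {path}"])
        issues = []
        for rec in self.records.values():
            for role, parent, sex in (("sire", rec.sire, "M"), ("dam", rec.dam, "F")):
                if parent is None:
                    continue
                if parent not in self.records:
                    issues.append(f"{rec.id}: {role} {parent} not in pedigree")
                    continue
                prec = self.records[parent]
                if prec.sex is not None and prec.sex != sex:
                    issues.append(f"{rec.id}: {role} {parent} has sex {prec.sex}")
                if (
                    prec.birth_year is not None
                    and rec.birth_year is not None
                    and prec.birth_year >= rec.birth_year
                ):
                    issues.append(
                        f"{rec.id}: born {rec.birth_year} not after {role} "
                        f"{parent} born {prec.birth_year}"
                    )
        return issues

    # -- structure ---------------------------------------------------------

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        rec = self.records[ind]
        sire = rec.sire if rec.sire in self.records else None
        dam = rec.dam if rec.dam in self.records else None
        return sire, dam

    @property
    def founders(self) -> list[str]:
        """Individuals with both parents unknown."""
        return [i for i in self.records if self.parents(i) == (None, None)]

    def phantom_parents(self, ind: str) -> list[str]:
        """Phantom founder labels for the unknown parent slots of a
        non-founder individual."""
        sire, dam = self.parents(ind)
        if sire is None and dam is None:
            return []
        out = []
        if sire is None:
            out.append(f"phantom:{ind}:sire")
        if dam is None:
            out.append(f"phantom:{ind}:dam")
        return out

    @property
    def topological_order(self) -> list[str]:
        """Parents before offspring."""
        return list(self._order)

    def reference_population(self, ids=None) -> list[str]:
        """Explicit id list, or the default: individuals with no progeny."""
        if ids is not None:
            ids = list(ids)
            unknown = [i for i in ids if i not in self.records]
            if unknown:
                raise KeyError(f"reference ids not in pedigree: {unknown}")
            if not ids:
                raise ValueError("empty reference population")
            return ids
        tips = [i for i in self.records if self._graph.out_degree(i) == 0]
        if not tips:
            raise ValueError("empty reference population")
        return tips

    def ancestors_of(self, ids) -> set[str]:
        out: set[str] = set()
        for i in ids:
            out |= nx.ancestors(self._graph, i)
        return out


# -- inbreeding ------------------------------------------------------------


def inbreeding_coefficients(ped: Pedigree, reference=None) -> tuple[pd.Series, float]:
    """Per-individual inbreeding F and its mean over the reference
    population.  F_i is the Malecot kinship of i's parents; an unknown
    parent contributes no identity by descent."""
    rank = {ind: k for k, ind in enumerate(ped.topological_order)}
    memo: dict[tuple[str, str], float] = {}

    def kinship(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            sa, da = ped.parents(a)
            return 0.5 * (1.0 + kinship(sa, da))
        if rank[a] > rank[b]:
            a, b = b, a
        key = (a, b)
        if key not in memo:
            sb, db = ped.parents(b)
            memo[key] = 0.5 * (kinship(a, sb) + kinship(a, db))
        return memo[key]

    values = {}
    for ind in ped.topological_order:
        sire, dam = ped.parents(ind)
        values[ind] = kinship(sire, dam)
    series = pd.Series(values, name="F")
    ref = ped.reference_population(reference)
    return series, float(series[ref].mean())


# -- founder contributions -------------------------------------------------


def _origin_vectors(ped: Pedigree, stop: set[str]) -> dict[str, dict[str, float]]:
    """Expected gene-origin distribution for every individual, with the
    upward recursion absorbed at founders, phantoms and ``stop`` nodes."""
    vectors: dict[str, dict[str, float]] = {}
    for ind in ped.topological_order:
        sire, dam = ped.parents(ind)
        if ind in stop or (sire is None and dam is None):
            vectors[ind] = {ind: 1.0}
            continue
        vec: dict[str, float] = {}
        for parent, phantom in ((sire, f"phantom:{ind}:sire"), (dam, f"phantom:{ind}:dam")):
            if parent is None:
                vec[phantom] = vec.get(phantom, 0.0) + 0.5
            else:
                for k, v in vectors[parent].items():
                    vec[k] = vec.get(k, 0.0) + 0.5 * v
        vectors[ind] = vec
    return vectors


def founder_contributions(ped: Pedigree, reference=None) -> tuple[pd.Series, float]:
    """Expected genome proportions q_k per founder (phantoms included)
    over the reference population, and f_e = 1 / sum(q_k^2)."""
    ref = ped.reference_population(reference)
    vectors = _origin_vectors(ped, stop=set())
    totals: dict[str, float] = {}
    for ind in ref:
        for k, v in vectors[ind].items():
            totals[k] = totals.get(k, 0.0) + v / len(ref)
    q = pd.Series(totals, name="q").sort_values(ascending=False)
    f_e = 1.0 / float((q**2).sum())
    return q, f_e


def effective_ancestors(
    ped: Pedigree,
    reference=None,
    *,
    epsilon: float = 1e-6,
    max_rounds: int | None = None,
) -> tuple[pd.Series, float]:
    """Marginal ancestor contributions p_j and f_a = 1 / sum(p_j^2).

    Iterative greedy selection: each round computes, for every
    not-yet-selected individual, its expected contribution to the
    reference gene pool counting only descent paths that avoid
    previously selected ancestors (their parent links are severed), and
    selects the maximum.  Stops when the best remaining marginal
    contribution falls below ``epsilon`` or the gene pool is fully
    explained.
    """
    ref = ped.reference_population(reference)
    weight = 1.0 / len(ref)
    reverse = list(reversed(ped.topological_order))
    severed: set[str] = set()
    selected: dict[str, float] = {}
    explained = 0.0
    max_rounds = max_rounds if max_rounds is not None else len(ped.records)
    for _ in range(max_rounds):
        contrib = {ind: 0.0 for ind in ped.records}
        for ind in ref:
            contrib[ind] += weight
        for ind in reverse:
            if ind in severed:
                continue
            sire, dam = ped.parents(ind)
            if sire is not None:
                contrib[sire] += 0.5 * contrib[ind]
            if dam is not None:
                contrib[dam] += 0.5 * contrib[ind]
        candidates = {i: c for i, c in contrib.items() if i not in selected}
        if not candidates:
            break
        best = max(sorted(candidates), key=lambda i: candidates[i])
        p = candidates[best]
        if p < epsilon:
            break
        selected[best] = p
        severed.add(best)
        explained += p
        if explained >= 1.0 - epsilon:
            break
    p_series = pd.Series(selected, name="p").sort_values(ascending=False)
    f_a = 1.0 / float((p_series**2).sum())
    return p_series, f_a


# -- gene dropping ---------------------------------------------------------


@dataclass(frozen=True)
class GeneDropResult:
    n_g: float
    standard_error: float      # Monte-Carlo SE of N_g (delta method)
    mean_homozygosity: float   # E[sum_a p_a^2]
    replicates: int


def founder_genomes(
    ped: Pedigree,
    reference=None,
    *,
    replicates: int = 10_000,
    seed: int,
) -> GeneDropResult:
    """Founder genome equivalents N_g by gene dropping.

    Each founder (and phantom parent) carries two uniquely labelled
    alleles; every replicate transmits alleles Mendelian-randomly down
    the pedigree, allele frequencies p_a are computed over the
    reference population, and N_g = 1 / (2 * mean(sum_a p_a^2)).
    Bit-for-bit reproducible for a fixed seed and replicate count.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ref = ped.reference_population(reference)
    rng = np.random.default_rng(seed)

    next_allele = 0

    def fresh_pair():
        nonlocal next_allele
        pair = (next_allele, next_allele + 1)
        next_allele += 2
        return pair

    alleles: dict[str, np.ndarray] = {}  # ind -> (replicates, 2) int32
    for ind in ped.topological_order:
        sire, dam = ped.parents(ind)
        carried = np.empty((replicates, 2), dtype=np.int64)
        for col, parent in enumerate((sire, dam)):
            if parent is None and sire is None and dam is None:
                a0, a1 = fresh_pair()
                carried[:, 0] = a0
                carried[:, 1] = a1
                break
            if parent is None:
                a0, a1 = fresh_pair()
                pick = rng.integers(0, 2, size=replicates)
                carried[:, col] = np.where(pick == 0, a0, a1)
            else:
                pick = rng.integers(0, 2, size=replicates)
                carried[:, col] = alleles[parent][np.arange(replicates), pick]
        alleles[ind] = carried

    pool = np.concatenate([alleles[i] for i in ref], axis=1)  # (reps, 2N)
    total = pool.shape[1]
    homozygosity = np.empty(replicates)
    for r in range(replicates):
        counts = np.bincount(pool[r])
        p = counts[counts > 0] / total
        homozygosity[r] = float((p**2).sum())
    mean_h = float(homozygosity.mean())
    se_h = float(homozygosity.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
    n_g = 1.0 / (2.0 * mean_h)
    se_ng = se_h / (2.0 * mean_h**2)  # delta method
    return GeneDropResult(n_g=n_g, standard_error=se_ng, mean_homozygosity=mean_h, replicates=replicates)


# -- simple summaries ------------------------------------------------------


def completeness(ped: Pedigree) -> float:
    """Fraction of pedigree records with both parents known."""
    both = sum(1 for i in ped.records if None not in ped.parents(i))
    return both / len(ped.records)


def matriline_expected_haplotype(ped: Pedigree, founder_haplotypes: dict[str, str]) -> pd.Series:
    """Expected mtDNA haplotype per individual by strict dam-line descent.

    ``founder_haplotypes`` maps dam-line founder ids to haplotype
    names.  Individuals whose matriline reaches an unknown dam are
    ``untraceable``; a matriline ending in a foundress absent from the
    map raises ``KeyError`` (unmapped matriline).
    """
    expected: dict[str, str] = {}
    for ind in ped.topological_order:
        _, dam = ped.parents(ind)
        if dam is None:
            rec = ped.records[ind]
            if rec.dam is not None:
                expected[ind] = "untraceable"  # dam recorded but not in pedigree
            elif ind in founder_haplotypes:
                expected[ind] = founder_haplotypes[ind]
            elif rec.sex == "F" or any(
                r.dam == ind for r in ped.records.values()
            ):
                raise KeyError(f"unmapped matriline founder: {ind}")
            else:
                expected[ind] = "untraceable"  # male founder, no matriline below
        else:
            expected[ind] = expected[dam]
    return pd.Series(expected, name="expected_haplotype")


# -- Table-2-style summary -------------------------------------------------


@dataclass(frozen=True)
class GeneOriginResult:
    """Bundle of the diversity statistics reported for a reference year."""

    reference_size: int
    total_founders: int         # founders + phantom parents contributing
    total_ascendants: int       # strict ancestors of the reference population
    q: pd.Series
    f_e: float
    p: pd.Series
    f_a: float
    n_g: float
    n_g_se: float
    ratio_fe_fa: float          # bottleneck indicator
    ratio_ng_fe: float          # genetic-drift indicator
    average_inbreeding: float
    completeness: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Reference animals", self.reference_size),
            ("Total founders", self.total_founders),
            ("Total ascendants", self.total_ascendants),
            ("Equivalent founders (f_e)", round(self.f_e, 2)),
            ("Effective ascendants (f_a)", round(self.f_a, 2)),
            ("f_e/f_a (bottlenecks)", round(self.ratio_fe_fa, 2)),
            ("Founder genomes (N_g)", round(self.n_g, 2)),
            ("N_g/f_e (genetic drift)", round(self.ratio_ng_fe, 4)),
            ("Average inbreeding", f"{100 * self.average_inbreeding:.2f}%"),
            ("Pedigree completeness", f"{100 * self.completeness:.1f}%"),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def gene_origin_summary(
    ped: Pedigree,
    reference=None,
    *,
    replicates: int = 10_000,
    seed: int,
) -> GeneOriginResult:
    """Compute the full diversity summary for one reference population."""
    ref = ped.reference_population(reference)
    q, f_e = founder_contributions(ped, ref)
    p, f_a = effective_ancestors(ped, ref)
    drop = founder_genomes(ped, ref, replicates=replicates, seed=seed)
    _, mean_f = inbreeding_coefficients(ped, ref)
    return GeneOriginResult(
        reference_size=len(ref),
        total_founders=len(q),
        total_ascendants=len(ped.ancestors_of(ref)),
        q=q,
        f_e=f_e,
        p=p,
        f_a=f_a,
        n_g=drop.n_g,
        n_g_se=drop.standard_error,
        ratio_fe_fa=f_e / f_a,
        ratio_ng_fe=drop.n_g / f_e,
        average_inbreeding=mean_f,
        completeness=completeness(ped),
    )
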