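"""Haplotype-to-maternal-family assignment.

A closed stud that wants to keep every historical maternal family *and*
every observed mtDNA haplotype needs a one-to-one association between
the two, even though recording errors scatter each haplotype over
several pedigree families.  This module builds the family x haplotype
contingency table, runs the iterative assignment procedure
(uniqueness -> exclusion -> majority -> tie), verifies the result
against an exhaustive matching oracle, and reports which mares are
retained (haplotype concordant with their recorded family) or culled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

__all__ = [
    "ContingencyTable",
    "HaplotypeAssignment",
    "AssignmentMap",
    "RetentionReport",
    "build_contingency",
    "assign_families",
    "matching_oracle",
    "retention",
    "haplotype_frequencies",
    "NoDataError",
    "InfeasibleCoverError",
]


class NoDataError(ValueError):
    """Empty mare table."""


class InfeasibleCoverError(ValueError):
    """No assignment can cover every family and use every haplotype."""

    def __init__(self, uncoverable):
        self.uncoverable = tuple(uncoverable)
        super().__init__(f"families with no observed haplotype: {self.uncoverable}")


@dataclass(frozen=True)
class ContingencyTable:
    """Mare counts per (maternal family, haplotype) combination."""

    counts: pd.DataFrame  # families x haplotypes, non-negative ints

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate family or haplotype labels")
        if (c.values < 0).any():
            raise ValueError("negative counts")
        if c.values.sum() <= 0:
            raise NoDataError("contingency table is empty")

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def support(self, haplotype: str) -> set[str]:
        """Families in which the haplotype was observed at least once."""
        col = self.counts[haplotype]
        return set(col.index[col > 0])


@dataclass(frozen=True)
class HaplotypeAssignment:
    haplotype: str
    families: frozenset[str]   # singleton, or several on an unresolved tie
    rule: str                  # unique-support | exclusion | majority | tie | unassignable
    step: int


@dataclass(frozen=True)
class AssignmentMap:
    assignments: dict[str, HaplotypeAssignment]
    families_without_haplotype: tuple[str, ...]

    def families_of(self, haplotype: str) -> frozenset[str]:
        a = self.assignments.get(haplotype)
        return a.families if a is not None else frozenset()

    def family_to_haplotype(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for a in self.assignments.values():
            for fam in a.families:
                out[fam] = a.haplotype
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype": a.haplotype,
                "families": ";".join(sorted(a.families)),
                "rule": a.rule,
                "step": a.step,
            }
            for a in sorted(self.assignments.values(), key=lambda x: (x.step, x.haplotype))
        ]
        return pd.DataFrame(rows, columns=["haplotype", "families", "rule", "step"])


def build_contingency(mares) -> ContingencyTable:
    """Tabulate (sample_id, family, haplotype) records into a table.

    Accepts any iterable of triples or a DataFrame with columns
    ``sample_id``, ``family``, ``haplotype``.  Row and column order is
    first-appearance order of the input, so a permuted input yields the
    same table up to label order.
    """
    if isinstance(mares, pd.DataFrame):
        df = mares[["sample_id", "family", "haplotype"]].copy()
    else:
        df = pd.DataFrame(list(mares), columns=["sample_id", "family", "haplotype"])
    if df.empty:
        raise NoDataError("no mare records")
    if df[["family", "haplotype"]].isna().any().any():
        raise ValueError("every mare needs family and haplotype labels")
    counts = pd.crosstab(df["family"], df["haplotype"])
    counts = counts.reindex(
        index=pd.unique(df["family"]), columns=pd.unique(df["haplotype"]), fill_value=0
    )
    counts.index.name = "family"
    counts.columns.name = "haplotype"
    return ContingencyTable(counts.astype(int))


def assign_families(table: ContingencyTable) -> AssignmentMap:
    """Iteratively associate each haplotype with a maternal family.

    The procedure runs to a fixed point over two rules.  A haplotype's
    *support* is the set of families where it was observed that are not
    yet taken by another haplotype.

    Rule A (uniqueness / exclusion): any haplotype whose support is a
    singleton claims that family; repeat until no change.  A haplotype
    whose support was a singleton already in the raw table is labelled
    ``unique-support``; one whose support shrank to a singleton because
    other families were claimed is labelled ``exclusion``.

    Rule B (majority): among still-open haplotypes having a *unique*
    most-frequent family in their support, the one with the largest
    such count (ties broken by largest margin over its second-best
    family, then by haplotype name) claims its most-frequent family;
    control returns to rule A.  When no open haplotype has a unique
    argmax, the haplotype with the largest count takes its tied
    families as a shared assignment (rule ``tie``); tied families are
    withdrawn from other supports only if those supports retain an
    alternative.

    Families observed in the table but assigned to no haplotype are
    flagged, not raised.
    """
    open_haps = sorted(table.haplotypes)
    initial_singleton = {h for h in open_haps if len(table.support(h)) == 1}
    taken: set[str] = set()
    result: dict[str, HaplotypeAssignment] = {}
    step = 0

    def support(h: str) -> dict[str, int]:
        col = table.counts[h]
        return {f: int(col[f]) for f in col.index if col[f] > 0 and f not in taken}

    while open_haps:
        # Rule A to exhaustion.
        changed = True
        while changed:
            changed = False
            for h in list(open_haps):
                sup = support(h)
                if len(sup) == 1:
                    fam = next(iter(sup))
                    step += 1
                    rule = "unique-support" if h in initial_singleton else "exclusion"
                    result[h] = HaplotypeAssignment(h, frozenset({fam}), rule, step)
                    taken.add(fam)
                    open_haps.remove(h)
                    changed = True
                elif len(sup) == 0:
                    step += 1
                    result[h] = HaplotypeAssignment(h, frozenset(), "unassignable", step)
                    open_haps.remove(h)
                    changed = True
        if not open_haps:
            break
        # Rule B: prefer haplotypes whose majority family is unique.
        def keyed(h: str):
            sup = support(h)
            counts = sorted(sup.values(), reverse=True)
            top = counts[0]
            margin = top - (counts[1] if len(counts) > 1 else 0)
            return top, margin

        unique_argmax = []
        for h in open_haps:
            sup = support(h)
            top = max(sup.values())
            if sum(1 for v in sup.values() if v == top) == 1:
                unique_argmax.append(h)
        if unique_argmax:
            h = min(unique_argmax, key=lambda x: (-keyed(x)[0], -keyed(x)[1], x))
            sup = support(h)
            fam = max(sup, key=lambda f: sup[f])
            step += 1
            result[h] = HaplotypeAssignment(h, frozenset({fam}), "majority", step)
            taken.add(fam)
            open_haps.remove(h)
            continue
        # Tie: no open haplotype has a unique majority family.
        h = min(open_haps, key=lambda x: (-keyed(x)[0], x))
        sup = support(h)
        top = max(sup.values())
        tied = frozenset(f for f, v in sup.items() if v == top)
        step += 1
        result[h] = HaplotypeAssignment(h, tied, "tie", step)
        open_haps.remove(h)
        # Withdraw a tied family from the open pool only when every open
        # haplotype observed in it still has an alternative family.
        for fam in tied:
            dependants = [o for o in open_haps if fam in support(o)]
            if all(set(support(o)) - tied for o in dependants):
                taken.add(fam)

    assigned_families = {f for a in result.values() for f in a.families}
    nonzero = {f for f in table.families if table.counts.loc[f].sum() > 0}
    missing = tuple(sorted(nonzero - assigned_families))
    return AssignmentMap(result, missing)


def matching_oracle(table: ContingencyTable) -> tuple[AssignmentMap, int]:
    """Exhaustive search for the retention-maximising assignment.

    Enumerates every map family -> haplotype drawn from each family's
    observed haplotypes, subject to: every haplotype is used, and a
    haplotype covering several families is allowed only when each of
    those families has no alternative haplotype.  Returns the optimal
    assignment and the number of mares it retains.  Intended as an
    independent check of :func:`assign_families` on tables up to about
    12 x 12.
    """
    families = table.families
    haplotypes = set(table.haplotypes)
    supports = {}
    uncoverable = []
    for f in families:
        row = table.counts.loc[f]
        opts = [h for h in table.haplotypes if row[h] > 0]
        if not opts:
            uncoverable.append(f)
        supports[f] = opts
    if uncoverable:
        raise InfeasibleCoverError(uncoverable)

    best_score = -1
    best_choice = None
    alternatives = {f: set(supports[f]) for f in families}
    for choice in itertools.product(*(supports[f] for f in families)):
        used: dict[str, list[str]] = {}
        for f, h in zip(families, choice):
            used.setdefault(h, []).append(f)
        if set(used) != haplotypes:
            continue
        shared = [h for h, fs in used.items() if len(fs) > 1]
        if len(shared) > 1:
            continue
        if shared and any(alternatives[f] - {shared[0]} for f in used[shared[0]]):
            continue
        score = sum(int(table.counts.loc[f, h]) for f, h in zip(families, choice))
        if score > best_score:
            best_score = score
            best_choice = choice
    if best_choice is None:
        raise InfeasibleCoverError(families)
    by_hap: dict[str, set[str]] = {}
    for f, h in zip(families, best_choice):
        by_hap.setdefault(h, set()).add(f)
    assignments = {
        h: HaplotypeAssignment(h, frozenset(fs), "oracle", 0) for h, fs in by_hap.items()
    }
    return AssignmentMap(assignments, ()), best_score


@dataclass(frozen=True)
class RetentionReport:
    """Per-mare retained/culled statuses plus aggregate counts."""

    per_mare: pd.DataFrame  # sample_id, family, haplotype, status
    retained: int
    culled: int
    unassessable: int


def retention(mares, amap: AssignmentMap) -> RetentionReport:
    """Decide which mares stay: haplotype must be the one assigned to
    their recorded family (families sharing a tied haplotype both count).

    Mares whose haplotype is absent from the assignment map get status
    ``unassessable`` and are counted separately.
    """
    if isinstance(mares, pd.DataFrame):
        df = mares[["sample_id", "family", "haplotype"]].copy()
    else:
        df = pd.DataFrame(list(mares), columns=["sample_id", "family", "haplotype"])
    statuses = []
    for _, row in df.iterrows():
        fams = amap.families_of(row["haplotype"])
        if row["haplotype"] not in amap.assignments:
            statuses.append("unassessable")
        elif row["family"] in fams:
            statuses.append("retained")
        else:
            statuses.append("culled")
    df["status"] = statuses
    return RetentionReport(
        per_mare=df,
        retained=int((df["status"] == "retained").sum()),
        culled=int((df["status"] == "culled").sum()),
        unassessable=int((df["status"] == "unassessable").sum()),
    )


def haplotype_frequencies(table: ContingencyTable) -> pd.DataFrame:
    """Per-haplotype mare counts and percentages of the grand total.

    Percentages are rounded half-to-even to one decimal place.
    """
    totals = table.counts.sum(axis=0)
    grand = table.grand_total
    pct = [
        float((Decimal(100) * Decimal(int(n)) / Decimal(grand)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_EVEN))
        for n in totals
    ]
    return pd.DataFrame(
        {"haplotype": totals.index, "count": totals.values.astype(int), "percent": pct}
    )
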