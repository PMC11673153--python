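import numpy as np
import pytest

from studlines.fixtures import (
    build_motif_catalogue,
    default_haplogroup_rules,
    table1_records,
)
from studlines.pedigree import Pedigree, PedigreeRecord
from studlines.reference import synthetic_dloop_reference


@pytest.fixture(scope="session")
def ref():
    return synthetic_dloop_reference()


@pytest.fixture(scope="session")
def catalogue(ref):
    return build_motif_catalogue(ref)


@pytest.fixture(scope="session")
def haplogroup_rules(ref):
    return default_haplogroup_rules(ref)


@pytest.fixture(scope="session")
def table1():
    return table1_records()


def random_pedigree(rng: np.random.Generator, *, n_founders=10, n_generations=4,
                    per_generation=20, missing_parent_prob=0.0) -> Pedigree:
    """Random generational pedigree for oracle checks.

    Founders split evenly by sex; each later individual draws its sire
    and dam uniformly from the previous generations' males/females.
    """
    records = []
    males, females = [], []
    for i in range(n_founders):
        ind = f"F{i:03d}"
        sex = "M" if i % 2 == 0 else "F"
        records.append(PedigreeRecord(ind, None, None, sex, 1900))
        (males if sex == "M" else females).append(ind)
    counter = 0
    for gen in range(1, n_generations + 1):
        new_m, new_f = [], []
        for _ in range(per_generation):
            counter += 1
            ind = f"I{counter:04d}"
            sire = males[rng.integers(0, len(males))]
            dam = females[rng.integers(0, len(females))]
            if missing_parent_prob and rng.random() < missing_parent_prob:
                sire = None
            sex = "M" if rng.random() < 0.5 else "F"
            records.append(PedigreeRecord(ind, sire, dam, sex, 1900 + 5 * gen))
            (new_m if sex == "M" else new_f).append(ind)
        males = males + new_m
        females = females + new_f
    return Pedigree(records)


def wright_path_inbreeding(ped: Pedigree, ind: str, _memo=None) -> float:
    """Independent path-counting oracle for the inbreeding coefficient.

    Enumerates, for every common ancestor A of the parents, all pairs of
    ancestor paths that share no individual besides A and sums
    (1/2)^(n + n' + 1) (1 + F_A).
    """
    if _memo is None:
        _memo = {}
    if ind in _memo:
        return _memo[ind]
    sire, dam = ped.parents(ind)
    if sire is None or dam is None:
        _memo[ind] = 0.0
        return 0.0

    paths_memo: dict[tuple[str, str], list[tuple[str, ...]]] = {}

    def paths_up(x: str, a: str) -> list[tuple[str, ...]]:
        """All node paths x -> ... -> a following parent links."""
        key = (x, a)
        if key in paths_memo:
            return paths_memo[key]
        if x == a:
            out = [(x,)]
        else:
            out = []
            for p in ped.parents(x):
                if p is not None:
                    out.extend((x,) + tail for tail in paths_up(p, a))
        paths_memo[key] = out
        return out

    ancestors = (ped.ancestors_of([sire]) | {sire}) & (ped.ancestors_of([dam]) | {dam})
    total = 0.0
    for anc in ancestors:
        fa = wright_path_inbreeding(ped, anc, _memo)
        for p1 in paths_up(sire, anc):
            s1 = set(p1[:-1])
            for p2 in paths_up(dam, anc):
                if s1 & set(p2[:-1]):
                    continue
                n_edges = (len(p1) - 1) + (len(p2) - 1)
                total += 0.5 ** (n_edges + 1) * (1.0 + fa)
    _memo[ind] = total
    return total
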