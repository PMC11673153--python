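"""Gene-origin statistics against independent oracles.

Inbreeding is checked against Wright's path-counting formula computed
by explicit path enumeration; founder contributions against a plain
per-replicate gene-dropping loop; effective ancestors against a
from-scratch per-candidate recursion re-run every selection round; and
founder genome equivalents against exact enumeration of the Mendelian
transmission outcomes on tiny pedigrees.
"""

import itertools
import warnings

import numpy as np
import pytest

from studlines.pedigree import (
    Pedigree,
    PedigreeCycleError,
    PedigreeRecord,
    completeness,
    effective_ancestors,
    founder_contributions,
    founder_genomes,
    gene_origin_summary,
    inbreeding_coefficients,
    matriline_expected_haplotype,
)
from studlines.simulate import StudScenario, simulate_stud

from conftest import random_pedigree, wright_path_inbreeding


def quiet_sim(scenario):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_stud(scenario)


class TestValidation:
    def test_trio_valid_with_two_founders(self):
        ped = Pedigree(
            [PedigreeRecord("s"), PedigreeRecord("d"), PedigreeRecord("c", "s", "d")]
        )
        assert sorted(ped.founders) == ["d", "s"]
        assert ped.issues == []

    def test_cycle_is_a_hard_error(self):
        records = [
            PedigreeRecord("a", "b", None),
            PedigreeRecord("b", "c", None),
            PedigreeRecord("c", "a", None),
        ]
        with pytest.raises(PedigreeCycleError):
            Pedigree(records)

    def test_sex_conflict_and_dangling_parent_reported(self):
        records = [
            PedigreeRecord("s", sex="F"),           # used as a sire below
            PedigreeRecord("c", "s", "ghost"),
        ]
        ped = Pedigree(records, strict=False)
        assert any("sex" in issue for issue in ped.issues)
        assert any("ghost" in issue for issue in ped.issues)

    def test_simulated_stud_founder_count_matches_scenario(self):
        scenario = StudScenario(seed=11, generations=3)
        sim = quiet_sim(scenario)
        expected = len(scenario.family_names) * scenario.founders_per_family + scenario.male_founders
        assert len(sim.pedigree.founders) == expected


class TestInbreeding:
    def test_full_sib_mating_closed_form(self):
        ped = Pedigree([
            PedigreeRecord("s"), PedigreeRecord("d"),
            PedigreeRecord("a", "s", "d", "M"), PedigreeRecord("b", "s", "d", "F"),
            PedigreeRecord("x", "a", "b"),
        ])
        F, _ = inbreeding_coefficients(ped)
        assert F["x"] == pytest.approx(0.25)

    def test_parent_offspring_mating_closed_form(self):
        ped = Pedigree([
            PedigreeRecord("s", sex="M"), PedigreeRecord("d", sex="F"),
            PedigreeRecord("a", "s", "d", "F"), PedigreeRecord("x", "s", "a"),
        ])
        F, _ = inbreeding_coefficients(ped)
        assert F["x"] == pytest.approx(0.25)

    def test_matches_path_counting_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            ped = random_pedigree(
                rng,
                n_founders=int(rng.integers(6, 14)),
                n_generations=int(rng.integers(3, 6)),
                per_generation=int(rng.integers(8, 25)),
            )
            F, _ = inbreeding_coefficients(ped)
            memo = {}
            for ind in ped.records:
                assert F[ind] == pytest.approx(
                    wright_path_inbreeding(ped, ind, memo), abs=1e-12
                )


class TestFounderContributions:
    def test_trio_half_each(self):
        ped = Pedigree(
            [PedigreeRecord("s"), PedigreeRecord("d"), PedigreeRecord("c", "s", "d")]
        )
        q, f_e = founder_contributions(ped)
        assert q["s"] == pytest.approx(0.5)
        assert q["d"] == pytest.approx(0.5)
        assert f_e == pytest.approx(2.0)

    def test_equal_contributions_give_fe_equal_n(self):
        n = 8
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(n)])
        q, f_e = founder_contributions(ped)
        assert f_e == pytest.approx(n)

    def test_single_known_parent_routes_to_phantom(self):
        ped = Pedigree(
            [PedigreeRecord("d"), PedigreeRecord("c", None, "d")], strict=True
        )
        q, f_e = founder_contributions(ped, ["c"])
        assert q["d"] == pytest.approx(0.5)
        assert q["phantom:c:sire"] == pytest.approx(0.5)
        assert q.sum() == pytest.approx(1.0)

    def test_matches_gene_dropping_expectation(self):
        rng = np.random.default_rng(23)
        ped = random_pedigree(rng, n_founders=6, n_generations=3, per_generation=8)
        ref = ped.reference_population()
        q, _ = founder_contributions(ped, ref)
        # independent plain-python gene dropper
        py_rng = np.random.default_rng(99)
        reps = 4000
        totals = {k: 0.0 for k in q.index}
        order = ped.topological_order
        for _ in range(reps):
            alleles = {}
            for ind in order:
                s, d = ped.parents(ind)
                pair = []
                for parent in (s, d):
                    if parent is None:
                        pair.append(ind)  # own founder label
                    else:
                        pair.append(alleles[parent][py_rng.integers(0, 2)])
                alleles[ind] = pair
            pool = [a for i in ref for a in alleles[i]]
            for k in totals:
                totals[k] += pool.count(k) / len(pool)
        for k in q.index:
            mc = totals[k] / reps
            se = np.sqrt(max(mc * (1 - mc), 1e-6) / (reps * 2 * len(ref)))
            assert q[k] == pytest.approx(mc, abs=max(5 * se, 5e-3))


class TestEffectiveAncestors:
    def test_bottleneck_sire_dominates(self):
        records = [PedigreeRecord("sire", sex="M")]
        for i in range(10):
            records.append(PedigreeRecord(f"d{i}", sex="F"))
            records.append(PedigreeRecord(f"c{i}", "sire", f"d{i}"))
        ped = Pedigree(records)
        p, f_a = effective_ancestors(ped)
        _, f_e = founder_contributions(ped)
        assert p.index[0] == "sire"
        assert p.iloc[0] == pytest.approx(0.5)
        assert f_a < f_e

    def test_founders_as_reference_gives_fa_equal_fe(self):
        n = 6
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(n)])
        _, f_a = effective_ancestors(ped)
        _, f_e = founder_contributions(ped)
        assert f_a == pytest.approx(f_e) == pytest.approx(n)

    def test_matches_from_scratch_recomputation(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            ped = random_pedigree(rng, n_founders=6, n_generations=3, per_generation=6)
            ref = ped.reference_population()
            p, f_a = effective_ancestors(ped, ref)

            # independent oracle: per-candidate downward-from-reference
            # recursion, recomputed from scratch every round
            selected: dict[str, float] = {}
            severed: set[str] = set()
            for _round in range(len(ped.records)):
                def contribution(j):
                    memo = {}
                    def c(i):
                        if i == j:
                            return 1.0
                        if i in severed:
                            return 0.0
                        if i not in memo:
                            s, d = ped.parents(i)
                            memo[i] = sum(0.5 * c(x) for x in (s, d) if x is not None)
                        return memo[i]
                    return sum(c(i) for i in ref) / len(ref)

                cands = {j: contribution(j) for j in ped.records if j not in selected}
                best = max(sorted(cands), key=lambda j: cands[j])
                if cands[best] < 1e-6:
                    break
                selected[best] = cands[best]
                severed.add(best)
                if sum(selected.values()) >= 1 - 1e-6:
                    break
            assert set(p.index) == set(selected)
            for j in selected:
                assert p[j] == pytest.approx(selected[j], abs=1e-9)


class TestFounderGenomes:
    def test_single_founder_reference_is_exactly_one(self):
        ped = Pedigree([PedigreeRecord("f")])
        res = founder_genomes(ped, ["f"], replicates=100, seed=0)
        assert res.n_g == pytest.approx(1.0)
        assert res.standard_error == pytest.approx(0.0)

    def test_n_unrelated_founders_give_n(self):
        n = 7
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(n)])
        res = founder_genomes(ped, replicates=50, seed=1)
        assert res.n_g == pytest.approx(n)

    def test_trio_matches_exact_transmission_enumeration(self):
        ped = Pedigree(
            [PedigreeRecord("s"), PedigreeRecord("d"), PedigreeRecord("c", "s", "d")]
        )
        # enumerate the 4 equally likely transmissions: the child always
        # carries one sire allele and one dam allele
        homs = []
        for si, di in itertools.product(range(2), range(2)):
            pool = [("s", si), ("d", di)]
            freqs = [pool.count(a) / len(pool) for a in set(pool)]
            homs.append(sum(f * f for f in freqs))
        exact = 1.0 / (2.0 * np.mean(homs))
        res = founder_genomes(ped, ["c"], replicates=100_000, seed=3)
        assert res.n_g == pytest.approx(exact, abs=3 * max(res.standard_error, 1e-12))

    def test_full_sib_pair_matches_exact_enumeration(self):
        ped = Pedigree([
            PedigreeRecord("s"), PedigreeRecord("d"),
            PedigreeRecord("c1", "s", "d"), PedigreeRecord("c2", "s", "d"),
        ])
        homs = []
        for a, b, x, y in itertools.product(range(2), repeat=4):
            pool = [("s", a), ("d", b), ("s", x), ("d", y)]
            freqs = [pool.count(al) / 4 for al in set(pool)]
            homs.append(sum(f * f for f in freqs))
        exact = 1.0 / (2.0 * np.mean(homs))
        res = founder_genomes(ped, ["c1", "c2"], replicates=100_000, seed=4)
        assert res.n_g == pytest.approx(exact, abs=3 * res.standard_error)

    def test_bitwise_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(41)
        ped = random_pedigree(rng, n_founders=8, n_generations=3, per_generation=10)
        a = founder_genomes(ped, replicates=500, seed=77)
        b = founder_genomes(ped, replicates=500, seed=77)
        assert a.n_g == b.n_g and a.mean_homozygosity == b.mean_homozygosity


class TestOrderingInvariant:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ng_le_fa_le_fe_le_founders(self, seed):
        sim = quiet_sim(StudScenario(seed=seed, generations=3))
        ped = sim.pedigree
        q, f_e = founder_contributions(ped)
        _, f_a = effective_ancestors(ped)
        res = founder_genomes(ped, replicates=400, seed=seed + 100)
        tol = 3 * res.standard_error
        assert res.n_g <= f_a + tol
        assert f_a <= f_e + 1e-9
        assert f_e <= len(q) + 1e-9


class TestCompleteness:
    def test_all_founders_zero(self):
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(4)])
        assert completeness(ped) == 0.0

    def test_trio_one_third(self):
        ped = Pedigree(
            [PedigreeRecord("s"), PedigreeRecord("d"), PedigreeRecord("c", "s", "d")]
        )
        assert completeness(ped) == pytest.approx(1 / 3)

    def test_matches_missing_sire_injection_log(self):
        scenario = StudScenario(seed=13, generations=3, missing_sire_rate=0.1)
        sim = quiet_sim(scenario)
        ped = sim.pedigree
        n = len(ped.records)
        expected = (n - len(ped.founders) - len(sim.missing_sire_ids)) / n
        assert completeness(ped) == pytest.approx(expected)


class TestMatriline:
    def test_three_generation_dam_line_propagates(self):
        ped = Pedigree([
            PedigreeRecord("gm", sex="F"),
            PedigreeRecord("sire", sex="M"),
            PedigreeRecord("m", "sire", "gm", "F"),
            PedigreeRecord("c", "sire", "m", "F"),
        ])
        expected = matriline_expected_haplotype(ped, {"gm": "HAP_A"})
        assert expected["gm"] == expected["m"] == expected["c"] == "HAP_A"

    def test_unmapped_foundress_raises(self):
        ped = Pedigree([PedigreeRecord("gm", sex="F"), PedigreeRecord("c", None, "gm")])
        with pytest.raises(KeyError):
            matriline_expected_haplotype(ped, {})

    def test_error_free_stud_has_zero_mismatches(self):
        sim = quiet_sim(StudScenario(seed=19, generations=3))
        expected = matriline_expected_haplotype(sim.pedigree, sim.founder_haplotypes)
        fam_map = sim.scenario.family_haplotypes
        mismatches = [
            i for i in sim.mares if expected[i] != fam_map[sim.recorded_family[i]]
        ]
        assert mismatches == []

    def test_label_errors_detected_exactly_where_injected(self):
        from studlines.fixtures import distinct_family_catalogue

        _, fam_map = distinct_family_catalogue()
        sim = quiet_sim(
            StudScenario(seed=29, generations=3, label_error_rate=0.08,
                         family_haplotypes=fam_map)
        )
        expected = matriline_expected_haplotype(sim.pedigree, sim.founder_haplotypes)
        flagged = {
            i for i in sim.mares if expected[i] != fam_map[sim.recorded_family[i]]
        }
        assert flagged == {e["sample_id"] for e in sim.error_log}


def test_summary_bundle_is_internally_consistent():
    sim = quiet_sim(StudScenario(seed=37, generations=3))
    res = gene_origin_summary(sim.pedigree, replicates=300, seed=5)
    assert res.q.sum() == pytest.approx(1.0)
    assert res.p.sum() <= 1.0 + 1e-9
    assert res.ratio_fe_fa == pytest.approx(res.f_e / res.f_a)
    assert res.ratio_ng_fe == pytest.approx(res.n_g / res.f_e)
    assert 0.0 <= res.average_inbreeding <= 1.0
    frame = res.to_frame()
    assert len(frame) == 10
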