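"""Coulomb Δ_prot and the protonation-ensemble Boltzmann correction."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from pchor.ensemble import (
    ChargeSet,
    MicrostatePopulation,
    SiteContributionTable,
    boltzmann_average_correction,
    coulomb_energy,
    delta_prot,
    group_sites,
    microstate_step_energy,
    population_from_samples,
    read_pqr,
    screen_by_effective_dielectric,
)
from pchor.synth import GeneratorSpec, gen_charge_fixture, gen_correlated_population
from pchor.thermo import CONSTANTS

RT300 = CONSTANTS.rt(300.0)


def brute_force_coulomb(cs, mask_i=None, mask_j=None):
    """O(N^2) double-loop reference."""
    n = cs.n_atoms
    mi = np.ones(n, bool) if mask_i is None else mask_i
    mj = np.ones(n, bool) if mask_j is None else mask_j
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (mi[i] and mj[j]) or (mi[j] and mj[i]):
                r = np.linalg.norm(cs.coordinates[i] - cs.coordinates[j])
                total += 332.0636 * cs.charges[i] * cs.charges[j] / r
    return total


def pair_set(q1, q2, r, regions=("ACTIVE", "ENVIRONMENT")):
    return ChargeSet(
        np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        np.array([q1, q2]),
        np.array(regions, dtype=object),
    )


class TestCoulomb:
    def test_unit_charges_at_calibrated_distance(self):
        assert coulomb_energy(pair_set(1.0, -1.0, 3.320636)) == pytest.approx(
            -100.0, abs=1e-9
        )

    def test_doubling_distance_halves_energy(self):
        e1 = coulomb_energy(pair_set(0.7, -0.3, 2.0))
        e2 = coulomb_energy(pair_set(0.7, -0.3, 4.0))
        assert e2 == pytest.approx(e1 / 2.0, abs=1e-12)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="zero interatomic"):
            coulomb_energy(pair_set(1.0, 1.0, 0.0))

    def test_matches_double_loop_on_random_fixtures(self):
        for seed in range(5):
            cs = gen_charge_fixture(GeneratorSpec(seed=seed, n_atoms=50))
            assert coulomb_energy(cs, "all") == pytest.approx(
                brute_force_coulomb(cs), abs=1e-8
            )

    def test_region_filters_partition_total(self):
        cs = gen_charge_fixture(GeneratorSpec(seed=1, n_atoms=30, n_active_atoms=8))
        total = coulomb_energy(cs, "all")
        parts = (
            coulomb_energy(cs, "active")
            + coulomb_energy(cs, "environment")
            + coulomb_energy(cs, "cross")
        )
        assert total == pytest.approx(parts, abs=1e-9)


class TestDeltaProt:
    def test_two_atom_case_is_the_pair_energy(self):
        cs = pair_set(0.5, -0.8, 3.0)
        assert delta_prot(cs) == pytest.approx(coulomb_energy(cs), abs=1e-12)

    def test_empty_environment_contributes_nothing(self):
        cs = pair_set(1.0, -1.0, 3.0, regions=("ACTIVE", "ACTIVE"))
        assert delta_prot(cs) == 0.0

    def test_distant_environment_cross_term_vanishes(self):
        cs = ChargeSet(
            np.array([[0.0, 0.0, 0.0], [1e6, 0.0, 0.0], [1e6 + 2.0, 0.0, 0.0]]),
            np.array([1.0, 0.5, -0.5]),
            np.array(["ACTIVE", "ENVIRONMENT", "ENVIRONMENT"], dtype=object),
        )
        assert delta_prot(cs, cross_only=True) == pytest.approx(0.0, abs=1e-3)

    def test_total_minus_active_identity(self):
        cs = gen_charge_fixture(GeneratorSpec(seed=2, n_atoms=40, n_active_atoms=12))
        assert delta_prot(cs) == pytest.approx(
            coulomb_energy(cs, "all") - coulomb_energy(cs, "active"), abs=1e-9
        )

    def test_matches_brute_force(self):
        cs = gen_charge_fixture(GeneratorSpec(seed=3, n_atoms=50, n_active_atoms=10))
        env = cs.mask("ENVIRONMENT")
        act = cs.mask("ACTIVE")
        expected = brute_force_coulomb(cs, env, env) / 1.0  # env self
        # add cross terms
        cross = 0.0
        for i in np.nonzero(act)[0]:
            for j in np.nonzero(env)[0]:
                r = np.linalg.norm(cs.coordinates[i] - cs.coordinates[j])
                cross += 332.0636 * cs.charges[i] * cs.charges[j] / r
        env_self = 0.0
        for i in np.nonzero(env)[0]:
            for j in np.nonzero(env)[0]:
                if j <= i:
                    continue
                r = np.linalg.norm(cs.coordinates[i] - cs.coordinates[j])
                env_self += 332.0636 * cs.charges[i] * cs.charges[j] / r
        assert delta_prot(cs) == pytest.approx(cross + env_self, abs=1e-8)
        assert delta_prot(cs, cross_only=True) == pytest.approx(cross, abs=1e-8)


class TestPQR:
    PQR = (
        "REMARK synthetic two-residue fixture\n"
        "ATOM      1  N   ASP A  274      10.000  11.000  12.000 -0.5163 1.8240\n"
        "ATOM      2  CA  ASP A  274      11.000  11.500  12.000  0.0381 1.9080\n"
        "HETATM    3  MG  PCH B  500       5.000   5.000   5.000  2.0000 1.4500\n"
    )
    PQR_NO_CHAIN = (
        "ATOM      1  N   ASP   274      10.000  11.000  12.000 -0.5163 1.8240\n"
        "ATOM      2  O   HOH   999       1.000   2.000   3.000 -0.8340 1.6612\n"
    )

    def test_chain_qualified_records(self):
        cs = read_pqr(io.StringIO(self.PQR), active_residues={"ASP_274"})
        assert cs.n_atoms == 3
        assert list(cs.regions) == ["ACTIVE", "ACTIVE", "ENVIRONMENT"]
        assert cs.charges[2] == 2.0
        assert cs.coordinates[0, 1] == 11.0

    def test_chainless_dialect(self):
        cs = read_pqr(io.StringIO(self.PQR_NO_CHAIN), active_residues={"ASP_274"})
        assert list(cs.regions) == ["ACTIVE", "ENVIRONMENT"]

    def test_agrees_with_mdanalysis_reader(self, tmp_path):
        # independent parser cross-check on the same synthetic fixture
        mda = pytest.importorskip("MDAnalysis")
        path = tmp_path / "fixture.pqr"
        path.write_text(self.PQR_NO_CHAIN)
        ours = read_pqr(path)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        assert np.allclose(ours.coordinates, u.atoms.positions, atol=1e-3)
        assert np.allclose(ours.charges, u.atoms.charges, atol=1e-6)

    def test_malformed_record_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            read_pqr(io.StringIO("ATOM 1 N ASP\n"))

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError, match="no ATOM"):
            read_pqr(io.StringIO("REMARK nothing\n"))


@pytest.fixture
def contrib3():
    return SiteContributionTable(
        pd.DataFrame(
            {"step1": [-5.0, 2.0, 0.5], "step2": [1.0, -1.0, 3.0]},
            index=["s0", "s1", "s2"],
        )
    )


class TestStepEnergies:
    def test_all_deprotonated_is_fixed_part(self, contrib3):
        assert microstate_step_energy(contrib3, "step1", [0, 0, 0], 2.0) == 2.0

    def test_single_contribution_adds(self, contrib3):
        assert microstate_step_energy(contrib3, "step1", [1, 0, 0], 2.0) == -3.0

    def test_additive_over_disjoint_sites(self, contrib3):
        e0 = microstate_step_energy(contrib3, "step2", [0, 0, 0])
        e_union = microstate_step_energy(contrib3, "step2", [1, 0, 1])
        singles = (
            microstate_step_energy(contrib3, "step2", [1, 0, 0])
            + microstate_step_energy(contrib3, "step2", [0, 0, 1])
        )
        assert e_union - e0 == pytest.approx(singles - 2 * e0, abs=1e-12)

    def test_unknown_site_rejected(self, contrib3):
        with pytest.raises(KeyError, match="unknown site"):
            microstate_step_energy(contrib3, "step1", {"ghost": 1})


class TestBoltzmannAverage:
    def test_certain_microstate_returns_its_energy(self, contrib3):
        pop = MicrostatePopulation([(("s0", "s1", "s2"), [((1, 0, 1), 1.0)])])
        got = boltzmann_average_correction(contrib3, "step1", pop)
        assert got == pytest.approx(-5.0 + 0.5, abs=1e-12)

    def test_degenerate_zero_states_average_to_zero(self):
        table = SiteContributionTable(
            pd.DataFrame({"s": [0.0]}, index=["a"])
        )
        pop = MicrostatePopulation([(("a",), [((0,), 0.5), ((1,), 0.5)])])
        assert boltzmann_average_correction(table, "s", pop) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_factorized_equals_full_enumeration_for_product_population(self):
        states, p, pop, ids = gen_correlated_population(
            GeneratorSpec(seed=5, correlation_strength=0.0), (6, 6)
        )
        rng = np.random.default_rng(9)
        flat = [i for g in ids for i in g]
        table = SiteContributionTable(
            pd.DataFrame({"step": rng.uniform(-25.0, 25.0, 12)}, index=flat)
        )
        fact = boltzmann_average_correction(table, "step", pop)
        de = states @ table.table["step"].to_numpy()
        full = -RT300 * logsumexp(-de / RT300, b=p)
        assert fact == pytest.approx(full, abs=1e-9)

    def test_discrepancy_grows_with_inter_group_correlation(self):
        rng = np.random.default_rng(9)
        contrib = rng.uniform(-25.0, 25.0, 12)
        gaps = []
        for alpha in (0.5, 2.0, 5.0):
            states, p, pop, ids = gen_correlated_population(
                GeneratorSpec(seed=5, correlation_strength=alpha), (6, 6)
            )
            flat = [i for g in ids for i in g]
            table = SiteContributionTable(
                pd.DataFrame({"step": contrib}, index=flat)
            )
            fact = boltzmann_average_correction(table, "step", pop)
            de = states @ contrib
            full = -RT300 * logsumexp(-de / RT300, b=p)
            gaps.append(abs(fact - full))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_average_bounded_by_extreme_contributions(self, rng):
        for _ in range(20):
            n = 6
            contrib = rng.uniform(-30.0, 30.0, n)
            table = SiteContributionTable(
                pd.DataFrame({"s": contrib}, index=[f"x{i}" for i in range(n)])
            )
            raw = rng.random(2**n)
            probs = raw / raw.sum()
            bits = np.arange(2**n, dtype=np.uint32)
            states = ((bits[:, None] >> np.arange(n)) & 1).astype(float)
            pop = MicrostatePopulation([
                (
                    tuple(f"x{i}" for i in range(n)),
                    [
                        (tuple(int(v) for v in s), float(q))
                        for s, q in zip(states, probs / probs.sum())
                    ],
                )
            ])
            avg = boltzmann_average_correction(table, "s", pop)
            de = states @ contrib
            assert de.min() - 1e-9 <= avg <= de.max() + 1e-9

    def test_relabeling_invariance(self, contrib3):
        pop1 = MicrostatePopulation([
            (("s0",), [((0,), 0.4), ((1,), 0.6)]),
            (("s1", "s2"), [((0, 0), 0.5), ((1, 1), 0.5)]),
        ])
        pop2 = MicrostatePopulation([
            (("s2", "s1"), [((0, 0), 0.5), ((1, 1), 0.5)]),
            (("s0",), [((1,), 0.6), ((0,), 0.4)]),
        ])
        a = boltzmann_average_correction(contrib3, "step1", pop1)
        b = boltzmann_average_correction(contrib3, "step1", pop2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unnormalized_population_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            MicrostatePopulation([(("a",), [((0,), 0.5), ((1,), 0.4)])])

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MicrostatePopulation([])

    def test_population_from_samples_counts_frequencies(self):
        samples = np.array([[0, 1], [0, 1], [1, 1], [0, 0]])
        pop = population_from_samples(samples, ["a", "b"], [["a"], ["b"]])
        states_a = dict(pop.groups[0][1])
        assert states_a[(0,)] == pytest.approx(0.75)
        assert states_a[(1,)] == pytest.approx(0.25)


class TestGrouping:
    def test_block_diagonal_blocks_recovered(self):
        ids = ["a", "b", "c", "d", "e"]
        c = np.eye(5)
        c[0, 1] = c[1, 0] = 0.8
        c[2, 3] = c[3, 2] = 0.6
        c[3, 4] = c[4, 3] = 0.5
        groups, neglected = group_sites(pd.DataFrame(c, index=ids, columns=ids))
        assert sorted(sorted(g) for g in groups) == [["a", "b"], ["c", "d", "e"]]
        assert neglected == 0.0

    def test_size_cap_forces_at_least_five_groups_for_44_sites(self, rng):
        n = 44
        ids = [f"s{i}" for i in range(n)]
        c = rng.uniform(0.05, 0.9, (n, n))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        groups, neglected = group_sites(
            pd.DataFrame(c, index=ids, columns=ids), max_group_size=10
        )
        assert len(groups) >= 5
        assert all(len(g) <= 10 for g in groups)
        assert 0.0 < neglected <= 0.9

    def test_zero_correlations_leave_singletons(self):
        ids = ["a", "b", "c"]
        groups, neglected = group_sites(
            pd.DataFrame(np.eye(3), index=ids, columns=ids)
        )
        assert sorted(map(tuple, groups)) == [("a",), ("b",), ("c",)]
        assert neglected == 0.0

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError, match="max_group_size"):
            group_sites(pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]), 0)


class TestScreening:
    def test_identity_and_halving(self):
        assert screen_by_effective_dielectric(-12.0, 1.0) == -12.0
        assert screen_by_effective_dielectric(-12.0, 2.0) == -6.0

    def test_sub_unity_dielectric_rejected(self):
        with pytest.raises(ValueError):
            screen_by_effective_dielectric(-12.0, 0.9)

    def test_small_screening_shift_in_volts(self):
        # screening a stabilization ΔE_elec from ε_eff 1 -> 1.06 moves a
        # one-electron potential by −ΔE_elec·(1 − 1/1.06)/F volts
        de_elec = -50.0
        shift_kcal = screen_by_effective_dielectric(de_elec, 1.06) - de_elec
        shift_v = -shift_kcal / CONSTANTS.faraday
        assert shift_v == pytest.approx(
            de_elec * (1 - 1 / 1.06) / CONSTANTS.faraday, abs=1e-12
        )
        assert shift_v == pytest.approx(-0.1227, abs=1e-4)
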