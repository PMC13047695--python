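import numpy as np
import pytest

from cgnmr import fixtures
from cgnmr.errors import DegenerateGeometryError
from cgnmr.io_formats import NOERecord, NOETable
from cgnmr.restraint_noe import (
    CGRestraint,
    NOEForceProvider,
    aggregate_bead_pair,
    apparent_distance,
    build_cg_restraints,
    condense_group,
    filter_conflicts,
    map_atom_pair,
    noe_energy,
    noe_force_magnitude,
    noe_timeavg_force,
    restraints_from_bead_table,
    update_running_average,
)

from conftest import finite_difference_forces


class TestMapAtomPair:
    def test_atoms_on_beads_true_distance(self):
        a_i, a_j = np.array([0.0, 0, 0]), np.array([0.6, 0, 0])
        d = map_atom_pair(a_i, a_j, a_i, a_j, 0.6)
        assert d == pytest.approx(0.6)

    def test_atoms_on_beads_arbitrary_d(self):
        a_i, a_j = np.array([0.0, 0, 0]), np.array([0.6, 0, 0])
        assert map_atom_pair(a_i, a_j, a_i, a_j, 0.45) == pytest.approx(0.45)

    def test_random_offsets_match_vector_oracle(self, rng):
        for _ in range(50):
            Ai, Aj, ai, aj = rng.normal(size=(4, 3))
            d_ij = float(rng.uniform(0.2, 1.0))
            unit = (aj - ai) / np.linalg.norm(aj - ai)
            expected = np.linalg.norm((ai - Ai) + d_ij * unit + (Aj - aj))
            got = map_atom_pair(Ai, Aj, ai, aj, d_ij)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_coincident_atoms_raise(self):
        p = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            map_atom_pair(p, p + 1, p, p, 0.5)


class TestApparentDistance:
    def test_single_distance_identity(self):
        assert apparent_distance([0.7]) == pytest.approx(0.7)

    def test_two_equal_closed_form(self):
        assert apparent_distance([0.5, 0.5]) == pytest.approx(
            0.5 * 2 ** (-1 / 6))

    def test_never_exceeds_minimum(self, rng):
        for _ in range(200):
            d = rng.uniform(0.1, 2.0, size=rng.integers(1, 8))
            assert apparent_distance(d) <= d.min() + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            apparent_distance([])


class TestCondense:
    def test_equal_contributors(self):
        assert condense_group([1.3, 1.3, 1.3], [0.2, 0.3, 0.4]) == \
            pytest.approx(1.3)

    def test_printed_two_contributor_example(self):
        expected = (1.0 * 0.2 ** -6 + 2.0 * 0.4 ** -6) / (
            0.2 ** -6 + 0.4 ** -6)
        assert condense_group([1.0, 2.0], [0.2, 0.4]) == \
            pytest.approx(expected)

    def test_short_distance_dominates(self):
        d = condense_group([1.0, 2.0], [1e-3, 0.4])
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_zero_atomistic_distance_raises(self):
        with pytest.raises(DegenerateGeometryError):
            condense_group([1.0], [0.0])


class TestAggregate:
    def test_single_signal(self):
        assert aggregate_bead_pair([0.9]) == pytest.approx(0.9)

    def test_mean(self):
        assert aggregate_bead_pair([1.0, 2.0]) == pytest.approx(1.5)

    def test_matches_accumulation(self, rng):
        vals = rng.uniform(0.2, 2.0, size=17)
        acc, n = 0.0, 0
        for v in vals:
            acc += v
            n += 1
        assert aggregate_bead_pair(vals) == pytest.approx(acc / n)


class TestFilterConflicts:
    def _setup(self, peptide):
        atoms, mapping = fixtures.pseudo_atomistic(peptide)
        return atoms, mapping

    def test_far_contributor_dropped(self, peptide):
        atoms, _ = self._setup(peptide)
        # record with contributors from residues 1 and 8 to residue 5
        d1 = np.linalg.norm(atoms.coords[atoms.atom_index("A", 1, "BB")]
                            - atoms.coords[atoms.atom_index("A", 5, "BB")])
        d8 = np.linalg.norm(atoms.coords[atoms.atom_index("A", 8, "BB")]
                            - atoms.coords[atoms.atom_index("A", 5, "BB")])
        near, far = (1, 8) if d1 < d8 else (8, 1)
        d_near = min(d1, d8)
        rec = NOERecord(
            group_i=[("A", 1, "BB"), ("A", 8, "BB")],
            group_j=[("A", 5, "BB")],
            d=float(d_near), r0=0.0, r1=float(d_near) + 0.05,
            r2=float(d_near) + 0.55)
        slack = abs(d8 - d1) / 2       # far contributor beyond d + slack
        filtered, report = filter_conflicts(NOETable([rec]), atoms,
                                            slack=slack)
        assert report["dropped_contributors"] == 1
        assert filtered.records[0].group_i == [("A", near, "BB")]

    def test_all_within_slack_unchanged(self, peptide):
        atoms, _ = self._setup(peptide)
        rec = NOERecord(group_i=[("A", 1, "BB")], group_j=[("A", 5, "BB")],
                        d=5.0, r0=0.0, r1=5.0, r2=5.5)
        filtered, report = filter_conflicts(NOETable([rec]), atoms, 0.2)
        assert report["dropped_contributors"] == 0
        assert len(filtered) == 1

    def test_counts_balance(self, peptide):
        atoms, _ = self._setup(peptide)
        rec = NOERecord(
            group_i=[("A", 1, "BB"), ("A", 8, "BB")],
            group_j=[("A", 5, "BB")],
            d=0.01, r0=0.0, r1=0.05, r2=0.55)
        filtered, report = filter_conflicts(NOETable([rec]), atoms, 0.0)
        kept = sum(len(r.group_i) * len(r.group_j) for r in filtered)
        assert 2 - kept == report["dropped_contributors"] - \
            (0 if filtered.records else 0) or report["dropped_records"] == 1


class TestBuildRestraints:
    def test_identity_mapping_preserves_bounds(self, peptide):
        atoms, mapping = fixtures.pseudo_atomistic(peptide)
        noe = fixtures.synth_noe_table(peptide, n_pairs=4, seed=1)
        restraints = build_cg_restraints(atoms, mapping, peptide, noe)
        assert len(restraints) == 4
        for rst, rec in zip(restraints, noe.records):
            # atoms sit on their beads, so bounds carry over unchanged
            assert rst.r1 == pytest.approx(rec.r1, abs=1e-9)
            assert rst.r2 == pytest.approx(rec.r2, abs=1e-9)

    def test_same_bead_pair_aggregates_to_one(self, peptide):
        atoms, mapping = fixtures.pseudo_atomistic(peptide)
        noe = fixtures.synth_noe_table(peptide, n_pairs=1, seed=1)
        noe.records.append(noe.records[0])     # duplicate signal
        restraints = build_cg_restraints(atoms, mapping, peptide, noe)
        assert len(restraints) == 1

    def test_count_equals_distinct_bead_pairs(self, peptide):
        atoms, mapping = fixtures.pseudo_atomistic(peptide)
        noe = fixtures.synth_noe_table(peptide, n_pairs=5, seed=2)
        restraints = build_cg_restraints(atoms, mapping, peptide, noe)
        pairs = {(r.bead_i, r.bead_j) for r in restraints}
        assert len(pairs) == len(restraints) == 5

    def test_unresolvable_atom_raises(self, peptide):
        atoms, mapping = fixtures.pseudo_atomistic(peptide)
        noe = NOETable([NOERecord([("A", 1, "XX")], [("A", 5, "BB")],
                                  0.5, 0.0, 0.5, 1.0)])
        with pytest.raises(KeyError):
            build_cg_restraints(atoms, mapping, peptide, noe)


class TestPotential:
    rst = CGRestraint(0, 1, 0.2, 0.5, 0.9, k=100.0)

    def test_flat_bottom_zero(self):
        for r in (0.21, 0.35, 0.499):
            assert noe_energy(r, self.rst) == 0.0

    def test_harmonic_below_r0(self):
        assert noe_energy(0.1, self.rst) == pytest.approx(
            0.5 * 100 * 0.1 ** 2)

    def test_continuity_at_r2_from_both_branches(self):
        k, r1, r2 = 100.0, 0.5, 0.9
        middle = 0.5 * k * (r2 - r1) ** 2
        linear = 0.5 * k * (r2 - r1) * (2 * r2 - r2 - r1)
        assert middle == pytest.approx(linear, abs=1e-12)
        assert noe_energy(r2, self.rst) == pytest.approx(middle)

    def test_c1_at_all_boundaries(self):
        for b in (0.2, 0.5, 0.9):
            below = noe_force_magnitude(b - 1e-9, self.rst)
            above = noe_force_magnitude(b + 1e-9, self.rst)
            assert below == pytest.approx(above, abs=1e-6)

    def test_constant_slope_beyond_r2(self):
        k, r1, r2 = 100.0, 0.5, 0.9
        for r in (0.95, 1.5, 3.0):
            assert noe_force_magnitude(r, self.rst) == pytest.approx(
                -k * (r2 - r1))

    def test_energy_nonnegative(self, rng):
        for r in rng.uniform(0.01, 3.0, size=200):
            assert noe_energy(float(r), self.rst) >= 0.0


class TestTimeAveraging:
    def test_constant_distance_fixed_point(self):
        # with the contract initialization r̄(0) = r, the average stays at r
        rst = CGRestraint(0, 1, 0.0, 0.5, 1.0, k=100.0, tau=0.05)
        r, dt = 0.8, 0.005
        for _ in range(int(10 * rst.tau / dt)):
            noe_timeavg_force(rst, r, dt)
        assert abs(rst.rbar - r) < 1e-6
        force = noe_timeavg_force(rst, r, dt)
        assert force == pytest.approx(noe_force_magnitude(r, rst), abs=1e-6)

    def test_perturbed_average_decays_to_distance(self):
        rst = CGRestraint(0, 1, 0.0, 0.5, 1.0, k=100.0, tau=0.05)
        rst.rbar = 1.4
        r, dt = 0.8, 0.005
        for _ in range(int(20 * rst.tau / dt)):
            noe_timeavg_force(rst, r, dt)
        assert abs(rst.rbar - r) < 1e-6

    def test_otherwise_branch_zero(self):
        # r below r0 but average above r1: no force
        rst = CGRestraint(0, 1, 0.3, 0.5, 1.0, k=100.0)
        rst.rbar = 0.8
        assert noe_timeavg_force(rst, 0.1, 1e-9) == 0.0

    def test_memoryless_limit_reduces_to_instantaneous(self):
        for r in (0.1, 0.7, 1.3):
            rst = CGRestraint(0, 1, 0.3, 0.5, 1.0, k=100.0, tau=1e-12)
            rst.rbar = 2.0
            got = noe_timeavg_force(rst, r, 0.01)
            assert got == pytest.approx(noe_force_magnitude(r, rst),
                                        abs=1e-6)

    def test_ramp_value_at_tau(self):
        rst = CGRestraint(0, 1, 0.0, 0.5, 1.0, k=100.0, ramp_tau=0.5)
        rst.rbar = 2.0
        got = noe_timeavg_force(rst, 2.0, 0.01, t=0.5, update=False)
        # pulling branch capped at r2-r1; K^t = K(1-1/e)
        expected = -100.0 * (1 - np.exp(-1.0)) * 0.5
        assert got == pytest.approx(expected, abs=1e-12)

    def test_running_average_in_inverse_cubed_space(self):
        rbar = update_running_average(1.0, 2.0, dt=0.05, tau=0.05)
        decay = np.exp(-1.0)
        expected = (decay * 1.0 + (1 - decay) * 2.0 ** -3) ** (-1 / 3)
        assert rbar == pytest.approx(expected, abs=1e-12)


class TestProvider:
    def test_newtons_third_law(self, rng):
        rst = CGRestraint(0, 1, 0.2, 0.5, 0.9, k=100.0)
        prov = NOEForceProvider([rst])
        c = rng.normal(size=(2, 3))
        _, forces = prov.evaluate(c)
        np.testing.assert_allclose(forces[0], -forces[1], atol=1e-12)

    def test_energy_force_consistency(self, rng):
        rst = CGRestraint(0, 1, 0.2, 0.5, 0.9, k=100.0)
        prov = NOEForceProvider([rst])
        worst = 0.0
        for _ in range(20):
            c = rng.normal(size=(2, 3))
            _, forces = prov.evaluate(c)
            numeric = finite_difference_forces(
                lambda x: prov.evaluate(x)[0], c)
            scale = max(np.max(np.abs(numeric)), 1e-4)
            worst = max(worst, np.max(np.abs(forces - numeric)) / scale)
        assert worst < 1e-4

    def test_own_geometry_zero_energy(self, peptide):
        noe = fixtures.synth_noe_table(peptide, n_pairs=5, seed=1)
        restraints = restraints_from_bead_table(peptide, noe)
        prov = NOEForceProvider(restraints)
        energy, forces = prov.evaluate(peptide.coords)
        assert energy == 0.0
        assert np.all(forces == 0.0)

    def test_monotone_apparent_distance_property(self, rng):
        # decreasing any contributing distance never increases d̂
        for _ in range(100):
            d = rng.uniform(0.2, 2.0, size=5)
            base = apparent_distance(d)
            k = rng.integers(0, 5)
            d[k] *= 0.5
            assert apparent_distance(d) <= base + 1e-12
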