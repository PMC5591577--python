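"""Force-field unit and property tests: torsion form, nonbonded pairs,
region-decomposed totals and alchemical interpolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restfep.forcefield import (
    COULOMB_CONSTANT,
    AlchemicalMap,
    Atom,
    AtomEndpoints,
    EnergyDecomposition,
    OverlappingAtomsError,
    Region,
    TorsionTerm,
    ToySystem,
    interpolate,
    nonbonded_pair_energy,
    torsion_energy,
    total_energy,
)

from conftest import random_system


def brute_force_total(system, params=None):
    """Single-loop reference sum over every pair and torsion."""
    p = params if params is not None else system.default_params()
    total = 0.0
    for idx in range(system.pair_i.size):
        i, j = int(system.pair_i[idx]), int(system.pair_j[idx])
        d = system.positions[i] - system.positions[j]
        r2 = float(d @ d)
        sig6 = (p.sigma[i] * p.sigma[j]) ** 3
        eps = math.sqrt(p.epsilon[i] * p.epsilon[j])
        r6 = r2**3 + p.sc_shift[i] + p.sc_shift[j]
        sr6 = sig6 / r6
        total += system.pair_scale[idx] * (
            4 * eps * (sr6 * sr6 - sr6)
            + COULOMB_CONSTANT * p.charge[i] * p.charge[j] / math.sqrt(r2)
        )
    for t_idx, term in enumerate(system.torsions):
        v = p.torsion_v[t_idx]
        total += torsion_energy(
            system.torsion_angle(t_idx), TorsionTerm(term.atom_ids, *v)
        )
    return total


class TestTorsionEnergy:
    @pytest.mark.parametrize(
        "angle, v, expected",
        [
            (180.0, (1.0, 0.0, 0.0), 0.0),
            (0.0, (1.0, 0.0, 0.0), 1.0),
            (90.0, (0.0, 2.0, 0.0), 2.0),
            (60.0, (0.0, 0.0, 3.0), 0.0),  # 3-fold minimum
        ],
    )
    def test_reference_values(self, angle, v, expected):
        term = TorsionTerm((0, 1, 2, 3), *v)
        assert torsion_energy(angle, term) == pytest.approx(expected, abs=1e-12)

    @given(
        angle=st.floats(-720, 720, allow_nan=False),
        v1=st.floats(-3, 3), v2=st.floats(-3, 3), v3=st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_periodicity(self, angle, v1, v2, v3):
        term = TorsionTerm((0, 1, 2, 3), v1, v2, v3)
        assert torsion_energy(angle, term) == pytest.approx(
            torsion_energy(angle + 360.0, term), abs=1e-10
        )

    def test_nonnegative_for_nonnegative_amplitudes(self):
        term = TorsionTerm((0, 1, 2, 3), 0.7, 1.3, 0.2)
        for angle in np.linspace(0, 360, 361):
            assert torsion_energy(angle, term) >= -1e-12


class TestPairEnergy:
    def _atom(self, i, pos, q=0.0, sigma=3.0, eps=0.0):
        return Atom(i, pos, q, sigma, eps, Region.LIGAND)

    def test_lj_zero_at_sigma(self):
        a = self._atom(0, (0, 0, 0), sigma=3.0, eps=0.5)
        b = self._atom(1, (3.0, 0, 0), sigma=3.0, eps=0.5)
        assert nonbonded_pair_energy(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth(self):
        r = 2 ** (1 / 6) * 3.0
        a = self._atom(0, (0, 0, 0), sigma=3.0, eps=0.2)
        b = self._atom(1, (r, 0, 0), sigma=3.0, eps=0.2)
        assert nonbonded_pair_energy(a, b) == pytest.approx(-0.2, abs=1e-12)

    def test_coulomb_value(self):
        a = self._atom(0, (0, 0, 0), q=0.5)
        b = self._atom(1, (5.0, 0, 0), q=0.5)
        assert nonbonded_pair_energy(a, b) == pytest.approx(
            332.06 * 0.25 / 5.0, abs=1e-9
        )

    def test_scale14_applies_to_both_terms(self):
        a = self._atom(0, (0, 0, 0), q=0.3, sigma=3.0, eps=0.2)
        b = self._atom(1, (4.0, 0, 0), q=-0.2, sigma=3.0, eps=0.1)
        assert nonbonded_pair_energy(a, b, scale14=0.5) == pytest.approx(
            0.5 * nonbonded_pair_energy(a, b), rel=1e-12
        )

    def test_overlap_raises(self):
        a = self._atom(0, (1, 1, 1))
        b = self._atom(1, (1, 1, 1))
        with pytest.raises(OverlappingAtomsError):
            nonbonded_pair_energy(a, b)

    def test_decay_to_zero(self):
        a = self._atom(0, (0, 0, 0), q=0.3, eps=0.2)
        b = self._atom(1, (250.0, 0, 0), q=0.3, eps=0.2)
        # LJ is negligible here and Coulomb falls off as 1/r
        assert abs(nonbonded_pair_energy(a, b)) < 332.06 * 0.09 / 249.0


class TestTotalEnergy:
    def test_all_environment_has_no_solute_terms(self, rng):
        atoms = [
            Atom(i, tuple(rng.uniform(-5, 5, 3)), 0.1, 3.0, 0.1,
                 Region.ENVIRONMENT)
            for i in range(5)
        ]
        system = ToySystem(atoms, [[i] for i in range(5)], [])
        d = total_energy(system)
        assert d.e_ss == 0.0 and d.e_sw == 0.0
        assert d.e_ww == pytest.approx(brute_force_total(system), abs=1e-9)

    def test_cross_pair_is_sw(self):
        atoms = [
            Atom(0, (0, 0, 0), 0.2, 3.0, 0.1, Region.LIGAND),
            Atom(1, (4, 0, 0), -0.2, 3.0, 0.1, Region.ENVIRONMENT),
        ]
        system = ToySystem(atoms, [[0], [1]], [])
        d = total_energy(system)
        assert d.e_ss == 0.0 and d.e_ww == 0.0
        assert d.e_sw == pytest.approx(
            nonbonded_pair_energy(atoms[0], atoms[1]), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(20))
    def test_decomposition_matches_brute_force(self, trial):
        rng = np.random.default_rng(500 + trial)
        system = random_system(rng)
        d = total_energy(system)
        assert d.total == pytest.approx(brute_force_total(system), abs=1e-9)
        assert d.e_ss + d.e_sw + d.e_ww == pytest.approx(d.total, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        system = random_system(rng)
        e0 = total_energy(system).total
        # translate + rotate everything rigidly
        from restfep.forcefield import _rotate_about_axis

        system.positions = _rotate_about_axis(
            system.positions + np.array([3.0, -2.0, 1.0]),
            np.array([1.0, 1.0, 1.0]),
            np.array([0.3, -0.5, 0.8]),
            1.234,
        )
        assert total_energy(system).total == pytest.approx(e0, abs=1e-9)

    def test_torsion_only_scope_moves_hot_pairs_to_environment(self, rng):
        system = random_system(rng)
        full = total_energy(system, hot_residue_scope="full")
        narrow = total_energy(system, hot_residue_scope="torsion_only")
        assert narrow.total == pytest.approx(full.total, abs=1e-9)
        # the chain torsion spans ligand+hot atoms: still tempered (ss)
        assert narrow.e_ss != 0.0


class TestSystemGeometry:
    def test_set_torsion_roundtrip(self, rng):
        system = random_system(rng)
        for target in (0.0, 90.0, 123.456, 359.0):
            system.set_torsion(0, target)
            assert system.torsion_angle(0) == pytest.approx(target, abs=1e-9)

    def test_torsion_rotation_moves_only_one_side(self, rng):
        system = random_system(rng)
        before = system.positions.copy()
        system.rotate_torsion(0, 30.0)
        moved = np.abs(system.positions - before).sum(axis=1) > 1e-12
        assert set(np.nonzero(moved)[0]) <= set(system.moving_atoms(0))

    def test_fragment_partition_enforced(self):
        atoms = [Atom(i, (float(i), 0, 0), 0, 3.0, 0.1, Region.LIGAND)
                 for i in range(3)]
        with pytest.raises(ValueError, match="partition"):
            ToySystem(atoms, [[0, 1]], [])

    def test_exclusion_pairs14_disjoint(self):
        atoms = [Atom(i, (float(i), 0, 0), 0, 3.0, 0.1, Region.LIGAND)
                 for i in range(2)]
        with pytest.raises(ValueError, match="disjoint"):
            ToySystem(atoms, [[0], [1]], [], exclusions=[(0, 1)],
                      pairs14=[(0, 1)])


class TestInterpolate:
    def _map(self, softcore=False):
        return AlchemicalMap(
            atoms={
                0: AtomEndpoints(0.0, 0.2, 3.0, 3.4, 0.1, 0.3,
                                 softcore=softcore)
            },
            torsions={0: ((1.0, 0.0, 0.0), (0.0, 2.0, 0.0))},
        )

    def test_endpoints_exact(self, rng):
        system = random_system(rng)
        amap = self._map()
        for lam, charge, sigma, eps in ((0.0, 0.0, 3.0, 0.1),
                                        (1.0, 0.2, 3.4, 0.3)):
            p = interpolate(system, amap, lam)
            assert p.charge[0] == charge
            assert p.sigma[0] == sigma
            assert p.epsilon[0] == eps
            assert p.sc_shift[0] == 0.0

    def test_midpoint_charge(self, rng):
        system = random_system(rng)
        p = interpolate(system, self._map(), 0.5)
        assert p.charge[0] == pytest.approx(0.1)
        assert np.allclose(p.torsion_v[0], [0.5, 1.0, 0.0])

    def test_lambda_range_checked(self, rng):
        system = random_system(rng)
        with pytest.raises(ValueError):
            interpolate(system, self._map(), 1.5)

    def test_softcore_forced_for_vanishing_atom(self):
        amap = AlchemicalMap(
            atoms={0: AtomEndpoints(0.0, 0.0, 3.0, 3.0, 0.0, 0.3)}
        )
        assert amap.atoms[0].softcore

    def test_softcore_shift_vanishes_at_coupled_endpoint(self, rng):
        system = random_system(rng)
        amap = AlchemicalMap(
            atoms={0: AtomEndpoints(0.0, 0.0, 3.0, 3.0, 0.0, 0.3)}
        )
        assert interpolate(system, amap, 1.0).sc_shift[0] == 0.0
        assert interpolate(system, amap, 0.0).sc_shift[0] > 0.0

    def test_endpoint_energy_matches_pure_system(self, rng):
        system = random_system(rng)
        amap = self._map()
        for lam, (q, sig, eps, v) in (
            (0.0, (0.0, 3.0, 0.1, (1.0, 0.0, 0.0))),
            (1.0, (0.2, 3.4, 0.3, (0.0, 2.0, 0.0))),
        ):
            pure = system.default_params()
            pure.charge[0], pure.sigma[0], pure.epsilon[0] = q, sig, eps
            pure.torsion_v[0] = v
            e_interp = total_energy(system, interpolate(system, amap, lam)).total
            assert e_interp == pytest.approx(
                total_energy(system, pure).total, abs=1e-12
            )

    def test_energy_continuous_in_lambda(self, rng):
        system = random_system(rng)
        amap = self._map()
        lams = np.linspace(0, 1, 21)
        es = [total_energy(system, interpolate(system, amap, l)).total
              for l in lams]
        assert np.abs(np.diff(es)).max() < 1.0


def test_energy_decomposition_arithmetic():
    a = EnergyDecomposition(1.0, 2.0, 3.0)
    b = EnergyDecomposition(0.5, -1.0, 2.0)
    assert (a + b).total == pytest.approx(7.5)
    assert (a - b).e_sw == pytest.approx(3.0)
    assert (-a).e_ss == -1.0
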