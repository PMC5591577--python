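"""REST tests: scaled-Hamiltonian algebra, swap acceptance, ground-
ensemble correctness and barrier-crossing enhancement."""

import math

import numpy as np
import pytest
from scipy import stats

from restfep.forcefield import BOLTZMANN_KCAL, EnergyDecomposition
from restfep.model_systems import boltzmann_density, make_rotor
from restfep.rest import (
    ReplicaLadder,
    RestState,
    _swap_delta,
    attempt_swap,
    run_rest,
    scaled_energy,
)
from restfep.sampler import ChainConfig, MarkovChain, MoveKind, MoveSpec, chain_rng, run_chain


class TestScaledEnergy:
    def test_identity_at_unit_ratio(self):
        d = EnergyDecomposition(10.0, 4.0, 2.0)
        assert scaled_energy(d, 1.0) == pytest.approx(16.0)

    def test_rest2_scaling_arithmetic(self):
        d = EnergyDecomposition(10.0, 4.0, 2.0)
        assert scaled_energy(d, 0.25) == pytest.approx(2.5 + 2.0 + 2.0)

    def test_environment_only_energy_unscaled(self):
        d = EnergyDecomposition(0.0, 0.0, 7.5)
        for r in (0.1, 0.5, 1.0):
            assert scaled_energy(d, r) == pytest.approx(7.5)

    @pytest.mark.parametrize("r", [0.0, -0.1, 1.5])
    def test_ratio_domain_enforced(self, r):
        with pytest.raises(ValueError):
            scaled_energy(EnergyDecomposition(1, 1, 1), r)


class TestLadder:
    def test_first_rung_is_thermal(self):
        with pytest.raises(ValueError, match="thermal"):
            ReplicaLadder((300.0, 600.0), thermal_temperature=298.15)

    def test_strictly_ascending(self):
        with pytest.raises(ValueError, match="ascending"):
            ReplicaLadder((298.15, 298.15), thermal_temperature=298.15)

    def test_geometric_spacing(self):
        lad = ReplicaLadder.geometric(4, 300.0, 2400.0)
        ts = lad.effective_temperatures
        ratios = [b / a for a, b in zip(ts, ts[1:])]
        assert all(r == pytest.approx(2.0) for r in ratios)
        assert lad.beta_ratio(0) == 1.0


class TestSwapDelta:
    def test_ww_cancels_algebraically(self, rng):
        """Environment-environment energy never enters the exchange
        exponent, whatever the scalings."""
        beta0 = 1.0 / (BOLTZMANN_KCAL * 298.15)
        for _ in range(50):
            ess_m, esw_m, ess_n, esw_n = rng.normal(size=4) * 10
            eww_m, eww_n = rng.normal(size=2) * 100
            r_m, r_n = sorted(rng.uniform(0.1, 1.0, 2))[::-1]
            d1 = _swap_delta(
                EnergyDecomposition(ess_m, esw_m, eww_m),
                EnergyDecomposition(ess_n, esw_n, eww_n),
                r_m, r_n, beta0,
            )
            d2 = _swap_delta(
                EnergyDecomposition(ess_m, esw_m, 0.0),
                EnergyDecomposition(ess_n, esw_n, 0.0),
                r_m, r_n, beta0,
            )
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_swap_symmetry(self, rng):
        """Delta for (m,n) equals Delta for (n,m) on the same pair."""
        beta0 = 1.0 / (BOLTZMANN_KCAL * 298.15)
        dm = EnergyDecomposition(3.0, 1.0, 5.0)
        dn = EnergyDecomposition(-1.0, 2.0, 4.0)
        assert _swap_delta(dm, dn, 1.0, 0.5, beta0) == pytest.approx(
            _swap_delta(dn, dm, 0.5, 1.0, beta0)
        )

    def test_hand_enumerated_two_replica_case(self):
        """Acceptance exponent from the four scaled energies by hand."""
        beta0 = 1.0 / (BOLTZMANN_KCAL * 298.15)
        dm = EnergyDecomposition(2.0, 1.0, 0.5)  # configuration x_m
        dn = EnergyDecomposition(6.0, -2.0, 0.3)  # configuration x_n
        r_m, r_n = 1.0, 0.25
        e_m = lambda d: scaled_energy(d, r_m)
        e_n = lambda d: scaled_energy(d, r_n)
        expected = beta0 * (e_m(dn) - e_m(dm) + e_n(dm) - e_n(dn))
        assert _swap_delta(dm, dn, r_m, r_n, beta0) == pytest.approx(expected)


def _rotor_chain_state(decomp, r, seed=0):
    """A MarkovChain whose cached decomposition is forced to a value,
    for swap bookkeeping tests."""
    system = make_rotor(0.0, 0.0, 0.0)
    chain = MarkovChain(
        system,
        [MoveSpec(MoveKind.TORSION, 0, 10.0)],
        298.15,
        chain_rng(seed),
        scale=(r, math.sqrt(r), 1.0),
    )
    chain.decomp = decomp
    return chain


class TestAttemptSwap:
    def _state(self, r_hot=0.25):
        ladder = ReplicaLadder((298.15, 298.15 / r_hot), swap_every=10)
        chains = [
            _rotor_chain_state(EnergyDecomposition(1.0, 0.0, 0.0), 1.0),
            _rotor_chain_state(EnergyDecomposition(5.0, 0.0, 0.0), r_hot),
        ]
        return RestState(chains=chains, ladder=ladder,
                         walker_of_replica=[0, 1])

    def test_identical_configurations_always_swap(self, rng):
        state = self._state()
        state.chains[1].decomp = EnergyDecomposition(1.0, 0.0, 0.0)
        assert attempt_swap(state, 0, 1, rng)

    def test_non_adjacent_pair_rejected(self, rng):
        ladder = ReplicaLadder((298.15, 500.0, 900.0))
        chains = [_rotor_chain_state(EnergyDecomposition(0, 0, 0), 1.0)
                  for _ in range(3)]
        state = RestState(chains=chains, ladder=ladder,
                          walker_of_replica=[0, 1, 2])
        with pytest.raises(ValueError, match="adjacent"):
            attempt_swap(state, 0, 2, rng)

    def test_acceptance_frequency_matches_exponent(self):
        """Empirical swap acceptance equals exp(-Delta) for Delta > 0."""
        beta0 = 1.0 / (BOLTZMANN_KCAL * 298.15)
        r_hot = 0.25
        dm = EnergyDecomposition(1.0, 0.0, 0.0)
        dn = EnergyDecomposition(2.0, 0.0, 0.0)
        delta = _swap_delta(dm, dn, 1.0, r_hot, beta0)
        assert delta > 0
        rng = np.random.default_rng(8)
        n, hits = 40000, 0
        state = self._state(r_hot)
        for _ in range(n):
            state.chains[0].decomp = dm
            state.chains[1].decomp = dn
            if attempt_swap(state, 0, 1, rng):
                hits += 1
        p = math.exp(-delta)
        assert abs(hits / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_configurations_exchanged_on_acceptance(self, rng):
        state = self._state()
        state.chains[1].decomp = EnergyDecomposition(-3.0, 0.0, 0.0)
        pos0 = state.chains[0].system.positions.copy()
        pos1 = state.chains[1].system.positions.copy()
        state.chains[1].system.positions += 0.5  # make them distinguishable
        pos1 += 0.5
        assert attempt_swap(state, 0, 1, rng)  # downhill: always accepted
        assert np.allclose(state.chains[0].system.positions, pos1)
        assert np.allclose(state.chains[1].system.positions, pos0)
        assert state.walker_of_replica == [1, 0]


class TestRunRest:
    _moves = [MoveSpec(MoveKind.TORSION, 0, 15.0, flip_probability=0.0)]

    def test_single_replica_reproduces_plain_chain(self):
        system = make_rotor(0.4, 0.9, 0.0)
        cfg = ChainConfig(n_steps=3000, seed=13, record_every=5)
        plain = run_chain(system, self._moves, cfg)
        ladder = ReplicaLadder((298.15,))
        rest = run_rest(system, ladder, self._moves, cfg)
        assert np.array_equal(plain.angles, rest.ground.angles)
        assert np.array_equal(plain.e_ss, rest.ground.e_ss)

    def test_equal_temperature_pair_always_swaps(self):
        # two rungs at nearly identical effective temperature: Delta ~ 0
        system = make_rotor(0.4, 0.9, 0.0)
        ladder = ReplicaLadder((298.15, 298.15 + 1e-9), swap_every=20)
        cfg = ChainConfig(n_steps=2000, seed=3)
        out = run_rest(system, ladder, self._moves, cfg)
        assert out.swap_rates()[(0, 1)] == 1.0

    def test_empty_hot_region_rejected(self, rng):
        from conftest import random_system
        from restfep.forcefield import Atom, Region, ToySystem

        atoms = [
            Atom(0, (0.0, 0, 0), 0.0, 3.0, 0.1, Region.ENVIRONMENT,
                 mobile=True),
            Atom(1, (4.0, 0, 0), 0.0, 3.0, 0.1, Region.ENVIRONMENT),
        ]
        system = ToySystem(atoms, [[0], [1]], [])
        ladder = ReplicaLadder.geometric(2)
        cfg = ChainConfig(n_steps=100, seed=1)
        move = [MoveSpec(MoveKind.TRANSLATE, (0,), 0.1)]
        with pytest.raises(ValueError, match="hot region"):
            run_rest(system, ladder, move, cfg)

    def test_permutation_history_is_bijection(self):
        system = make_rotor(0.0, 3.0, 0.0)
        ladder = ReplicaLadder.geometric(4, swap_every=50)
        cfg = ChainConfig(n_steps=2000, seed=21)
        out = run_rest(system, ladder, self._moves, cfg)
        assert out.permutation_history
        for perm in out.permutation_history:
            assert sorted(perm) == [0, 1, 2, 3]

    def test_ground_marginal_matches_quadrature_despite_ladder(self):
        """Demuxed replica-0 ensemble of a high-barrier double well must
        match the thermal Boltzmann density and reach 50/50 occupancy,
        while an equal-length plain chain stays trapped."""
        amps = (0.0, 8.0, 0.0)  # wells at 0/180, barrier ~13.5 kT
        system = make_rotor(*amps, initial_angle=0.0)
        cfg = ChainConfig(n_steps=30000, seed=11, record_every=10)
        plain = run_chain(system, self._moves, cfg)
        ang = plain.angle(0)
        trapped = np.mean((ang > 90) & (ang < 270))
        assert trapped < 0.1  # plain chain never crosses

        ladder = ReplicaLadder.geometric(6, 298.15, 1200.0, swap_every=100)
        rest = run_rest(system, ladder, self._moves, cfg)
        ang = rest.ground.angle(0)
        in_far_well = np.mean((ang > 90) & (ang < 270))
        # binomial 3-sigma with a conservative effective sample size
        assert abs(in_far_well - 0.5) < 3 * 0.5 / math.sqrt(100)

        theta, dens = boltzmann_density(amps, cfg.temperature)
        edges = np.linspace(0, 360, 13)
        counts, _ = np.histogram(ang[::10], bins=edges)
        probs = np.array([
            dens[(theta >= lo) & (theta < hi)].sum() * (theta[1] - theta[0])
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        probs /= probs.sum()
        keep = probs > 1e-4  # ignore essentially-forbidden barrier bins
        p = stats.chisquare(counts[keep],
                            probs[keep] / probs[keep].sum()
                            * counts[keep].sum()).pvalue
        assert p > 0.01
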