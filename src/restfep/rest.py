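"""Hamiltonian replica exchange with solute tempering (REST).

Only the hot region's interactions are scaled: with the
effective-temperature ratio r = beta_m / beta_0, replica m samples

    E_m = r * E_ss + sqrt(r) * E_sw + E_ww

(the REST2 scaling), so barriers internal to the ligand and to the
designated flexible residue are flattened at the high rungs while the
environment stays cold.  All replicas run at the same thermal
temperature; exchanges swap configurations between neighbouring rungs
with the Hamiltonian-exchange criterion

    Delta = beta_0 [ E_m(x_n) - E_m(x_m) + E_n(x_m) - E_n(x_n) ],

accepted with probability min(1, exp(-Delta)).  Because the
environment-environment energy enters every rung unscaled, it cancels
exactly in Delta.

The rung at r = 1 (replica 0) samples the physical Boltzmann ensemble;
its frames are the "demultiplexed" ground ensemble that all free-energy
estimators consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import BOLTZMANN_KCAL, EnergyDecomposition, NonbondedParams, ToySystem
from .sampler import ChainConfig, MarkovChain, MoveSpec, Trajectory, chain_rng

__all__ = [
    "ReplicaLadder",
    "RestState",
    "RestResult",
    "scaled_energy",
    "attempt_swap",
    "run_rest",
]


@dataclass(frozen=True)
class ReplicaLadder:
    """Effective-temperature ladder for solute tempering.

    The first effective temperature must equal the thermal temperature
    (that rung samples the physical ensemble) and the ladder must be
    strictly ascending.  ``swap_every`` is the number of MC steps
    between exchange attempts.
    """

    effective_temperatures: tuple[float, ...]
    thermal_temperature: float = 298.15
    swap_every: int = 100

    def __post_init__(self) -> None:
        ts = self.effective_temperatures
        if len(ts) < 1:
            raise ValueError("ladder needs at least one replica")
        if not math.isclose(ts[0], self.thermal_temperature):
            raise ValueError("first effective temperature must be thermal")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("effective temperatures must be strictly ascending")
        if self.swap_every <= 0:
            raise ValueError("swap_every must be > 0")

    @property
    def n_replicas(self) -> int:
        return len(self.effective_temperatures)

    def beta_ratio(self, m: int) -> float:
        """r = beta_m / beta_0 = T_0 / T_m for rung m."""
        return self.thermal_temperature / self.effective_temperatures[m]

    @classmethod
    def geometric(
        cls,
        n_replicas: int = 6,
        t_min: float = 298.15,
        t_max: float = 1200.0,
        swap_every: int = 100,
    ) -> "ReplicaLadder":
        """Geometric effective-temperature spacing from t_min to t_max."""
        if n_replicas == 1:
            return cls((t_min,), thermal_temperature=t_min, swap_every=swap_every)
        ts = t_min * (t_max / t_min) ** (np.arange(n_replicas) / (n_replicas - 1))
        return cls(tuple(float(t) for t in ts), thermal_temperature=t_min,
                   swap_every=swap_every)


def scaled_energy(decomp: EnergyDecomposition, beta_ratio: float) -> float:
    """REST2-scaled total energy for a rung with beta ratio r in (0, 1]."""
    if not 0.0 < beta_ratio <= 1.0:
        raise ValueError(f"beta ratio must be in (0, 1], got {beta_ratio}")
    r = beta_ratio
    return r * decomp.e_ss + math.sqrt(r) * decomp.e_sw + decomp.e_ww


def _swap_delta(
    decomp_m: EnergyDecomposition,
    decomp_n: EnergyDecomposition,
    r_m: float,
    r_n: float,
    beta0: float,
) -> float:
    """Exchange exponent for configurations x_m (at rung m) and x_n (at
    rung n).  The e_ww terms cancel algebraically and are never formed."""
    d_ss = decomp_n.e_ss - decomp_m.e_ss
    d_sw = decomp_n.e_sw - decomp_m.e_sw
    return beta0 * ((r_m - r_n) * d_ss + (math.sqrt(r_m) - math.sqrt(r_n)) * d_sw)


@dataclass
class RestState:
    """Mutable bookkeeping of a REST run: per-replica chains, swap
    statistics, and the replica -> walker permutation history."""

    chains: list[MarkovChain]
    ladder: ReplicaLadder
    swap_attempts: dict[tuple[int, int], int] = field(default_factory=dict)
    swap_accepts: dict[tuple[int, int], int] = field(default_factory=dict)
    walker_of_replica: list[int] = field(default_factory=list)
    permutation_history: list[tuple[int, ...]] = field(default_factory=list)


def attempt_swap(state: RestState, m: int, n: int, rng: np.random.Generator) -> bool:
    """Attempt a configuration exchange between adjacent rungs m and n.

    On acceptance the two replicas' configurations (coordinates, cached
    energies, torsion angles) are exchanged; the attempt counter is
    updated either way.
    """
    if abs(m - n) != 1:
        raise ValueError("only adjacent rungs may exchange")
    lad = state.ladder
    key = (min(m, n), max(m, n))
    state.swap_attempts[key] = state.swap_attempts.get(key, 0) + 1
    beta0 = 1.0 / (BOLTZMANN_KCAL * lad.thermal_temperature)
    delta = _swap_delta(
        state.chains[m].decomp,
        state.chains[n].decomp,
        lad.beta_ratio(m),
        lad.beta_ratio(n),
        beta0,
    )
    if delta <= 0.0 or rng.random() < math.exp(-delta):
        _exchange_configurations(state.chains[m], state.chains[n])
        state.walker_of_replica[m], state.walker_of_replica[n] = (
            state.walker_of_replica[n],
            state.walker_of_replica[m],
        )
        state.swap_accepts[key] = state.swap_accepts.get(key, 0) + 1
        return True
    return False


def _exchange_configurations(a: MarkovChain, b: MarkovChain) -> None:
    a.system.positions, b.system.positions = b.system.positions, a.system.positions
    a.angles, b.angles = b.angles, a.angles
    a.decomp, b.decomp = b.decomp, a.decomp


@dataclass
class RestResult:
    """Outcome of a REST run."""

    trajectories: list[Trajectory]  # one per rung; index 0 is the ground rung
    ladder: ReplicaLadder
    swap_attempts: dict[tuple[int, int], int]
    swap_accepts: dict[tuple[int, int], int]
    permutation_history: list[tuple[int, ...]]

    @property
    def ground(self) -> Trajectory:
        """The demultiplexed physical ensemble (replica 0 frames)."""
        return self.trajectories[0]

    def swap_rates(self) -> dict[tuple[int, int], float]:
        return {
            k: self.swap_accepts.get(k, 0) / n
            for k, n in self.swap_attempts.items()
        }


def run_rest(
    system: ToySystem,
    ladder: ReplicaLadder,
    moves: list[MoveSpec],
    cfg: ChainConfig,
    params: NonbondedParams | None = None,
    hot_residue_scope: str = "full",
    frame_hook=None,
) -> RestResult:
    """Run REST sampling and return per-rung trajectories.

    Exchange epochs alternate even and odd neighbour pairs.  Frames are
    recorded per rung on the shared schedule; ``frame_hook`` (see
    :func:`restfep.sampler.run_chain`) is applied to the ground rung
    only, since only the physical ensemble feeds the estimators.  With
    ``n_replicas = 1`` the run follows the identical random stream as a
    plain chain with the same seed.
    """
    if not system.solute_mask(hot_residue_scope).any():
        raise ValueError("REST hot region is empty")
    n_rep = ladder.n_replicas
    chains = [
        MarkovChain(
            system,
            moves,
            cfg.temperature,
            chain_rng(cfg.seed, stream=i),
            params=params,
            scale=_rest_scale(ladder.beta_ratio(i)),
            hot_residue_scope=hot_residue_scope,
        )
        for i in range(n_rep)
    ]
    state = RestState(
        chains=chains,
        ladder=ladder,
        walker_of_replica=list(range(n_rep)),
    )
    swap_rng = chain_rng(cfg.seed, stream=2**20)

    equil = int(cfg.equilibration_fraction * cfg.n_steps)
    buffers = [
        {"steps": [], "angles": [], "ess": [], "esw": [], "eww": [], "acc": [],
         "extras": {}}
        for _ in range(n_rep)
    ]

    epoch = 0
    last_accept = [False] * n_rep
    for s in range(1, cfg.n_steps + 1):
        for i, chain in enumerate(chains):
            last_accept[i] = chain.step()
        if s % ladder.swap_every == 0 and n_rep > 1:
            start = epoch % 2
            for m in range(start, n_rep - 1, 2):
                attempt_swap(state, m, m + 1, swap_rng)
            state.permutation_history.append(tuple(state.walker_of_replica))
            epoch += 1
        if s > equil and (s - equil) % cfg.record_every == 0:
            for i, chain in enumerate(chains):
                b = buffers[i]
                b["steps"].append(s)
                b["angles"].append(chain.angles.copy())
                d = chain.decomp
                b["ess"].append(d.e_ss)
                b["esw"].append(d.e_sw)
                b["eww"].append(d.e_ww)
                b["acc"].append(last_accept[i])
                if i == 0 and frame_hook is not None:
                    for key, val in frame_hook(chain).items():
                        b["extras"].setdefault(key, []).append(val)

    n_t = len(system.torsions)
    trajectories = []
    for i, b in enumerate(buffers):
        nf = len(b["steps"])
        trajectories.append(
            Trajectory(
                torsion_ids=list(range(n_t)),
                steps=np.array(b["steps"], dtype=int),
                angles=np.array(b["angles"]).reshape(nf, n_t) % 360.0,
                e_ss=np.array(b["ess"]),
                e_sw=np.array(b["esw"]),
                e_ww=np.array(b["eww"]),
                accepted=np.array(b["acc"], dtype=bool),
                acceptance=chains[i].acceptance_ratios(),
                extras={k: np.array(v) for k, v in b["extras"].items()},
            )
        )
    return RestResult(
        trajectories=trajectories,
        ladder=ladder,
        swap_attempts=dict(state.swap_attempts),
        swap_accepts=dict(state.swap_accepts),
        permutation_history=list(state.permutation_history),
    )


def _rest_scale(r: float) -> tuple[float, float, float]:
    return (r, math.sqrt(r), 1.0)
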