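"""Metropolis Monte Carlo over torsional and rigid-body degrees of freedom.

Moves are drawn from a weighted mix of rigid-body translations/rotations
of an atom group and single-torsion perturbations.  Torsion moves
propose either a small symmetric displacement or, with configurable
probability, a large-angle "flip" (+/-120 or 180 degrees) so that
jumps between rotamer wells are part of the proposal distribution --
the mechanism that lets alternative binding modes interconvert.

Energy differences are evaluated incrementally from only the
interactions involving moved atoms; rigid-body geometry guarantees that
intra-group terms are unchanged.  The chain records region-decomposed
energies so the same engine can run plain (unscaled) sampling and
REST-scaled replicas.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    BOLTZMANN_KCAL,
    COULOMB_CONSTANT,
    EnergyDecomposition,
    NonbondedParams,
    Region,
    ToySystem,
    dihedral_angle,
    total_energy,
)

__all__ = [
    "MoveKind",
    "MoveSpec",
    "ChainConfig",
    "Trajectory",
    "MarkovChain",
    "metropolis_accept",
    "propose_move",
    "run_chain",
    "default_move_mix",
]

_SS, _SW, _WW = 0, 1, 2


class MoveKind(enum.Enum):
    TRANSLATE = "translate"
    ROTATE = "rotate"
    TORSION = "torsion"


@dataclass(frozen=True)
class MoveSpec:
    """One entry of the Monte Carlo move mix.

    ``target`` is a torsion index for TORSION moves, or an atom group
    for rigid-body moves: either a :class:`Region` (all atoms with that
    label) or an explicit tuple of atom ids.  ``max_displacement`` is in
    Angstrom for TRANSLATE and degrees for ROTATE/TORSION.
    ``flip_probability`` applies to TORSION moves only: with that
    probability the proposal is a flip of +/-120 or 180 degrees instead
    of a small perturbation.  ``axis_weights`` restricts ROTATE moves:
    the random rotation axis is drawn with each component scaled by the
    corresponding weight, so (1, 1, 0) proposes only tilts about axes in
    the xy-plane -- used for pose-anchored complexes where wholesale
    spinning about the pocket axis would let the ligand bypass its
    torsional barriers unphysically.  The axis distribution does not
    depend on the configuration, so proposals stay symmetric.
    """

    kind: MoveKind
    target: int | Region | tuple[int, ...]
    max_displacement: float
    weight: float = 1.0
    flip_probability: float = 0.1
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.weight <= 0:
            raise ValueError("move weight must be > 0")


@dataclass(frozen=True)
class ChainConfig:
    """Run-length and bookkeeping parameters of one Markov chain."""

    n_steps: int
    seed: int
    temperature: float = 298.15
    record_every: int = 10
    equilibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")


@dataclass
class Trajectory:
    """Recorded frames of one chain plus acceptance bookkeeping."""

    torsion_ids: list[int]
    steps: np.ndarray
    angles: np.ndarray  # (frames, torsions), degrees in [0, 360)
    e_ss: np.ndarray
    e_sw: np.ndarray
    e_ww: np.ndarray
    accepted: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.steps.size)

    def angle(self, torsion_id: int) -> np.ndarray:
        return self.angles[:, self.torsion_ids.index(torsion_id)]

    def write_tsv(self, path) -> None:
        """Tab-separated table: step, one angle column per torsion,
        energy components and acceptance flag.  A ``.gz`` suffix writes
        gzip-compressed text."""
        import gzip
        import io

        cols = (
            ["step"]
            + [f"phi_{t}" for t in self.torsion_ids]
            + ["e_ss", "e_sw", "e_ww", "accepted"]
        )
        buf = io.StringIO()
        buf.write("\t".join(cols) + "\n")
        for f in range(self.n_frames):
            row = [str(int(self.steps[f]))]
            row += [f"{a:.6f}" for a in self.angles[f]]
            row += [
                f"{self.e_ss[f]:.8f}",
                f"{self.e_sw[f]:.8f}",
                f"{self.e_ww[f]:.8f}",
                str(int(self.accepted[f])),
            ]
            buf.write("\t".join(row) + "\n")
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(buf.getvalue())


def metropolis_accept(delta_e: float, temperature: float, rng_draw: float) -> bool:
    """Metropolis criterion: accept iff draw < min(1, exp(-dE/kT)).

    Non-positive energy changes are accepted unconditionally, which also
    guards the exponential against overflow.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0.0:
        return True
    return rng_draw < math.exp(-delta_e / (BOLTZMANN_KCAL * temperature))


@dataclass
class TrialMove:
    """A proposed perturbation: new coordinates for the moved atoms and
    the incremental energy change it would cause."""

    kind: MoveKind
    moved: np.ndarray  # atom indices
    new_positions: np.ndarray  # (len(moved), 3)
    delta: EnergyDecomposition
    torsion_index: int | None = None
    new_angle: float | None = None


class MarkovChain:
    """Mutable sampling state: system coordinates, effective parameters,
    cached energy decomposition and per-target interaction tables.

    ``scale`` holds the REST multipliers (s_ss, s_sw, s_ww) applied to
    the decomposed energy difference inside the Metropolis test; plain
    sampling uses (1, 1, 1).
    """

    def __init__(
        self,
        system: ToySystem,
        moves: list[MoveSpec],
        temperature: float,
        rng: np.random.Generator,
        params: NonbondedParams | None = None,
        scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
        hot_residue_scope: str = "full",
    ):
        if not moves:
            raise ValueError("at least one move spec required")
        self.system = system.copy()
        self.moves = list(moves)
        self.temperature = temperature
        self.rng = rng
        self.params = params if params is not None else system.default_params()
        self.scale = scale
        self.hot_residue_scope = hot_residue_scope

        w = np.array([m.weight for m in moves], dtype=float)
        self._cum_weights = np.cumsum(w / w.sum())

        self._pair_cls = system.pair_classes(hot_residue_scope)
        self._tors_cls = system.torsion_classes(hot_residue_scope)
        self._move_ctx = [self._prepare_move(m) for m in moves]
        self.angles = self.system.torsion_angles()
        self.decomp = total_energy(self.system, self.params, hot_residue_scope)
        self.n_proposed: dict[str, int] = {k.value: 0 for k in MoveKind}
        self.n_accepted: dict[str, int] = {k.value: 0 for k in MoveKind}

    # -- move preparation ----------------------------------------------------

    def _resolve_target(self, move: MoveSpec) -> np.ndarray:
        sys = self.system
        if move.kind is MoveKind.TORSION:
            t = int(move.target)
            if not 0 <= t < len(sys.torsions):
                raise ValueError(f"unknown torsion id {t}")
            atoms = np.array(sys.moving_atoms(t), dtype=int)
        elif isinstance(move.target, Region):
            atoms = np.array(sys.region_atoms(move.target), dtype=int)
        elif isinstance(move.target, tuple):
            atoms = np.array(move.target, dtype=int)
        else:
            atoms = np.array(sys.rigid_fragments[int(move.target)], dtype=int)
        if atoms.size == 0:
            raise ValueError(f"move target {move.target!r} selects no atoms")
        if not sys.mobile[atoms].all():
            raise ValueError(f"move target {move.target!r} includes immobile atoms")
        return atoms

    def _prepare_move(self, move: MoveSpec) -> dict:
        sys = self.system
        atoms = self._resolve_target(move)
        in_m = np.zeros(sys.n_atoms, dtype=bool)
        in_m[atoms] = True
        a_in = in_m[sys.pair_i]
        b_in = in_m[sys.pair_j]
        affected = np.nonzero(a_in ^ b_in)[0]  # exactly one end moves
        if move.kind is MoveKind.TORSION:
            tors = [int(move.target)]
        else:
            # torsions that straddle the moved group change their angle
            tors = [
                t
                for t, term in enumerate(sys.torsions)
                if 0 < int(in_m[list(term.atom_ids)].sum()) < 4
            ]
        return {"atoms": atoms, "pairs": affected, "torsions": tors}

    # -- energy pieces -------------------------------------------------------

    def _pairs_energy_by_class(self, rows: np.ndarray, positions: np.ndarray):
        sys, p = self.system, self.params
        i, j = sys.pair_i[rows], sys.pair_j[rows]
        d = positions[i] - positions[j]
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 == 0.0):
            return None  # overlap: caller rejects the move
        sig6 = (p.sigma[i] * p.sigma[j]) ** 3
        eps = np.sqrt(p.epsilon[i] * p.epsilon[j])
        r6 = r2 * r2 * r2 + p.sc_shift[i] + p.sc_shift[j]
        sr6 = sig6 / r6
        e = sys.pair_scale[rows] * (
            4.0 * eps * (sr6 * sr6 - sr6)
            + COULOMB_CONSTANT * p.charge[i] * p.charge[j] / np.sqrt(r2)
        )
        cls = self._pair_cls[rows]
        out = np.zeros(3)
        for c in (_SS, _SW, _WW):
            out[c] = e[cls == c].sum()
        return out

    def _torsions_energy_by_class(self, tors: list[int], angles: np.ndarray):
        out = np.zeros(3)
        v = self.params.torsion_v
        for t in tors:
            phi = math.radians(angles[t])
            e = (
                0.5 * v[t, 0] * (1.0 + math.cos(phi))
                + 0.5 * v[t, 1] * (1.0 - math.cos(2.0 * phi))
                + 0.5 * v[t, 2] * (1.0 + math.cos(3.0 * phi))
            )
            out[self._tors_cls[t]] += e
        return out

    # -- proposals -----------------------------------------------------------

    def propose(self, move_index: int) -> TrialMove | None:
        """Generate a trial move; ``None`` signals an instant reject
        (particle overlap in the trial configuration)."""
        move = self.moves[move_index]
        ctx = self._move_ctx[move_index]
        sys, rng = self.system, self.rng
        atoms = ctx["atoms"]
        pos = sys.positions
        t_idx = None
        new_angle = None

        if move.kind is MoveKind.TRANSLATE:
            disp = rng.uniform(-move.max_displacement, move.max_displacement, 3)
            new_pos = pos[atoms] + disp
        elif move.kind is MoveKind.ROTATE:
            axis = rng.normal(size=3) * move.axis_weights
            angle = rng.uniform(-move.max_displacement, move.max_displacement)
            centroid = pos[atoms].mean(axis=0)
            new_pos = _rodrigues(pos[atoms], centroid, axis, math.radians(angle))
        else:  # TORSION
            t_idx = int(move.target)
            if rng.random() < move.flip_probability:
                delta = float(rng.choice([-120.0, 120.0, 180.0]))
            else:
                delta = rng.uniform(-move.max_displacement, move.max_displacement)
            term = sys.torsions[t_idx]
            j, k = term.atom_ids[1], term.atom_ids[2]
            # axis k -> j: positive rotation increases the dihedral
            new_pos = _rodrigues(
                pos[atoms], pos[k], pos[j] - pos[k], math.radians(delta)
            )
            new_angle = (self.angles[t_idx] + delta) % 360.0

        rows = ctx["pairs"]
        e_old = (
            self._pairs_energy_by_class(rows, pos) if rows.size else np.zeros(3)
        )
        trial_full = pos.copy()
        trial_full[atoms] = new_pos
        e_new = (
            self._pairs_energy_by_class(rows, trial_full)
            if rows.size
            else np.zeros(3)
        )
        if e_new is None or e_old is None:
            return None
        d = e_new - e_old

        if ctx["torsions"]:
            old_t = self._torsions_energy_by_class(ctx["torsions"], self.angles)
            trial_angles = self.angles.copy()
            if move.kind is MoveKind.TORSION:
                trial_angles[t_idx] = new_angle
            else:
                for t in ctx["torsions"]:
                    ids = sys.torsions[t].atom_ids
                    trial_angles[t] = dihedral_angle(*(trial_full[a] for a in ids))
            new_t = self._torsions_energy_by_class(ctx["torsions"], trial_angles)
            d = d + (new_t - old_t)
            if move.kind is not MoveKind.TORSION:
                self._trial_angles = (ctx["torsions"], trial_angles)
            else:
                self._trial_angles = None
        else:
            self._trial_angles = None

        return TrialMove(
            kind=move.kind,
            moved=atoms,
            new_positions=new_pos,
            delta=EnergyDecomposition(*d),
            torsion_index=t_idx,
            new_angle=new_angle,
        )

    def scaled_delta(self, delta: EnergyDecomposition) -> float:
        s = self.scale
        return s[0] * delta.e_ss + s[1] * delta.e_sw + s[2] * delta.e_ww

    def step(self) -> bool:
        """One Metropolis step; returns whether the move was accepted."""
        rng = self.rng
        m = int(np.searchsorted(self._cum_weights, rng.random(), side="right"))
        m = min(m, len(self.moves) - 1)
        kind = self.moves[m].kind.value
        self.n_proposed[kind] += 1
        trial = self.propose(m)
        draw = rng.random()  # always drawn: keeps the stream aligned
        if trial is None:
            return False
        if not metropolis_accept(
            self.scaled_delta(trial.delta), self.temperature, draw
        ):
            return False
        self.system.positions[trial.moved] = trial.new_positions
        self.decomp = self.decomp + trial.delta
        if trial.torsion_index is not None:
            self.angles[trial.torsion_index] = trial.new_angle
        elif self._trial_angles is not None:
            tors, trial_angles = self._trial_angles
            for t in tors:
                self.angles[t] = trial_angles[t]
        self.n_accepted[kind] += 1
        return True

    def acceptance_ratios(self) -> dict[str, float]:
        return {
            k: (self.n_accepted[k] / n if (n := self.n_proposed[k]) else float("nan"))
            for k in self.n_proposed
        }


def _rodrigues(points, origin, axis, angle_rad):
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    v = np.asarray(points, dtype=float) - origin
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(k, v) * s + np.outer(v @ k, k) * (1.0 - c) + origin


def propose_move(
    system: ToySystem,
    move: MoveSpec,
    rng: np.random.Generator,
    params: NonbondedParams | None = None,
    temperature: float = 298.15,
) -> TrialMove:
    """Generate one trial move on ``system`` and its incremental energy
    change (solute/environment-decomposed).

    The proposal density is symmetric (forward and reverse perturbations
    are equally likely), as the Metropolis criterion requires.
    """
    chain = MarkovChain(system, [move], temperature, rng, params=params)
    trial = chain.propose(0)
    if trial is None:
        raise OverflowError("trial configuration has overlapping atoms")
    return trial


def chain_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-chain generator; distinct streams never collide."""
    return np.random.default_rng([int(seed), int(stream)])


def run_chain(
    system: ToySystem,
    moves: list[MoveSpec],
    cfg: ChainConfig,
    params: NonbondedParams | None = None,
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
    hot_residue_scope: str = "full",
    frame_hook=None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run one Metropolis chain and record frames.

    Frames are recorded every ``cfg.record_every`` steps after the first
    ``cfg.equilibration_fraction`` of the run is discarded.
    ``frame_hook(chain)``, if given, is called at every recorded frame
    and may return a dict of extra per-frame scalars (stored in
    ``Trajectory.extras``) -- the FEP driver uses this to evaluate
    perturbation energies on the fly.
    """
    if rng is None:
        rng = chain_rng(cfg.seed)
    chain = MarkovChain(
        system, moves, cfg.temperature, rng, params=params, scale=scale,
        hot_residue_scope=hot_residue_scope,
    )
    traj = _advance(chain, cfg.n_steps, cfg, frame_hook,
                    equil=int(cfg.equilibration_fraction * cfg.n_steps))
    return traj


def _advance(chain: MarkovChain, n_steps: int, cfg: ChainConfig, frame_hook, equil: int):
    steps, angles, ess, esw, eww, acc = [], [], [], [], [], []
    extras: dict[str, list] = {}
    for s in range(1, n_steps + 1):
        accepted = chain.step()
        if s > equil and (s - equil) % cfg.record_every == 0:
            steps.append(s)
            angles.append(chain.angles.copy())
            d = chain.decomp
            ess.append(d.e_ss)
            esw.append(d.e_sw)
            eww.append(d.e_ww)
            acc.append(accepted)
            if frame_hook is not None:
                for key, val in frame_hook(chain).items():
                    extras.setdefault(key, []).append(val)
    n_t = len(chain.system.torsions)
    traj = Trajectory(
        torsion_ids=list(range(n_t)),
        steps=np.array(steps, dtype=int),
        angles=(np.array(angles).reshape(len(steps), n_t) % 360.0),
        e_ss=np.array(ess),
        e_sw=np.array(esw),
        e_ww=np.array(eww),
        accepted=np.array(acc, dtype=bool),
        acceptance=chain.acceptance_ratios(),
        extras={k: np.array(v) for k, v in extras.items()},
    )
    return traj


def default_move_mix(
    system: ToySystem,
    flip_probability: float = 0.1,
) -> list[MoveSpec]:
    """The default move mix for a pocket complex: 40% ligand rigid-body
    (split evenly between translation <= 0.15 A and rotation <= 15 deg),
    40% ligand torsion perturbation (<= 15 deg), 20% hot-residue torsion.
    Systems lacking some degrees of freedom get the applicable subset.
    """
    lig = set(system.region_atoms(Region.LIGAND))
    hot = set(system.region_atoms(Region.HOT_RESIDUE))
    in_complex = bool(system.region_atoms(Region.ENVIRONMENT))
    moves: list[MoveSpec] = []
    if lig and system.mobile[sorted(lig)].all():
        moves.append(MoveSpec(MoveKind.TRANSLATE, Region.LIGAND, 0.15, weight=0.2,
                              flip_probability=0.0))
        # in a pocket the ligand pose is anchored: rotations are tilts
        # about transverse axes, never spins about the pocket (z) axis
        moves.append(MoveSpec(MoveKind.ROTATE, Region.LIGAND, 15.0, weight=0.2,
                              flip_probability=0.0,
                              axis_weights=(1.0, 1.0, 0.0) if in_complex
                              else (1.0, 1.0, 1.0)))
    for t, term in enumerate(system.torsions):
        ids = set(term.atom_ids)
        if ids & hot:
            moves.append(MoveSpec(MoveKind.TORSION, t, 15.0, weight=0.2,
                                  flip_probability=flip_probability))
        elif ids & lig:
            moves.append(MoveSpec(MoveKind.TORSION, t, 15.0, weight=0.4,
                                  flip_probability=flip_probability))
    if not moves:
        raise ValueError("system has no mobile degrees of freedom")
    return moves
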