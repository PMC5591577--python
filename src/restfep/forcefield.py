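"""Reduced OPLS-style potential energy model with region decomposition.

The model keeps only the terms needed for torsional binding-mode physics:
an OPLS Fourier torsion potential, Lennard-Jones 12-6 and Coulomb
nonbonded interactions with geometric combination rules, 0.5 scaling of
1-4 pairs, and no cutoffs or periodic boundary.  Bond lengths and angles
are rigid: a system is a set of rigid fragments connected by rotatable
bonds, so the only degrees of freedom are torsion angles and rigid-body
coordinates.

Every atom carries a region label (``LIGAND``, ``HOT_RESIDUE`` or
``ENVIRONMENT``).  The total energy is always evaluated decomposed into
solute-solute, solute-environment and environment-environment parts,
where "solute" means the REST hot region (ligand plus the designated
flexible residue); replica-exchange solute tempering scales these three
components with different powers of the effective-temperature ratio.

Alchemical single-topology mutations are described by an
:class:`AlchemicalMap` holding endpoint (state A / state B) nonbonded
and torsion parameters; :func:`interpolate` produces the effective
parameter set at a coupling parameter lambda, with a separation-shifted
soft-core Lennard-Jones form for atoms that vanish at an endpoint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "COULOMB_CONSTANT",
    "BOLTZMANN_KCAL",
    "SOFTCORE_ALPHA",
    "Region",
    "Atom",
    "TorsionTerm",
    "ToySystem",
    "EnergyDecomposition",
    "AlchemicalMap",
    "NonbondedParams",
    "OverlappingAtomsError",
    "torsion_energy",
    "nonbonded_pair_energy",
    "total_energy",
    "interpolate",
    "dihedral_angle",
]

#: Coulomb prefactor in kcal * Angstrom / (mol * e^2).
COULOMB_CONSTANT = 332.06
#: Boltzmann constant in kcal / (mol * K).
BOLTZMANN_KCAL = 0.0019872
#: Soft-core separation shift strength (dimensionless).
SOFTCORE_ALPHA = 0.5
#: OPLS-style scaling of 1-4 nonbonded pairs (both LJ and Coulomb).
SCALE_14 = 0.5


class OverlappingAtomsError(ValueError):
    """Two interacting particles are at zero separation."""


class Region(enum.IntEnum):
    LIGAND = 0
    HOT_RESIDUE = 1
    ENVIRONMENT = 2


# pair / torsion interaction classes for the energy decomposition
_SS, _SW, _WW = 0, 1, 2


@dataclass(frozen=True)
class Atom:
    """A point particle with OPLS-style nonbonded parameters.

    Parameters
    ----------
    id : int
        Unique atom index within the system (0-based, dense).
    position : 3-sequence of float
        Cartesian coordinates in Angstrom.
    charge : float
        Partial charge in elementary charge units.
    sigma : float
        Lennard-Jones diameter in Angstrom (> 0).
    epsilon : float
        Lennard-Jones well depth in kcal/mol (>= 0).
    region : Region
        REST region label.
    mobile : bool
        Whether any Monte Carlo move may displace the atom.
    """

    id: int
    position: tuple[float, float, float]
    charge: float
    sigma: float
    epsilon: float
    region: Region
    mobile: bool = True

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"atom {self.id}: sigma must be > 0")
        if self.epsilon < 0:
            raise ValueError(f"atom {self.id}: epsilon must be >= 0")


@dataclass
class TorsionTerm:
    """OPLS Fourier torsion on four sequentially bonded atoms.

    V(phi) = V1/2 (1 + cos phi) + V2/2 (1 - cos 2 phi) + V3/2 (1 + cos 3 phi)

    The rotatable bond is the j-k bond (``atom_ids[1]``-``atom_ids[2]``)
    and must join two different rigid fragments of the owning system.
    """

    atom_ids: tuple[int, int, int, int]
    v1: float = 0.0
    v2: float = 0.0
    v3: float = 0.0

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.v1, self.v2, self.v3)


def torsion_energy(angle_deg: float, term: TorsionTerm) -> float:
    """OPLS Fourier torsion energy at ``angle_deg`` (degrees), kcal/mol.

    Periodic with period 360 degrees; the angle is wrapped internally.
    """
    phi = math.radians(angle_deg)
    return (
        0.5 * term.v1 * (1.0 + math.cos(phi))
        + 0.5 * term.v2 * (1.0 - math.cos(2.0 * phi))
        + 0.5 * term.v3 * (1.0 + math.cos(3.0 * phi))
    )


def _torsion_energy_array(angles_deg: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised torsion energies; ``v`` has shape (T, 3), angles (T,)."""
    phi = np.radians(angles_deg)
    return (
        0.5 * v[:, 0] * (1.0 + np.cos(phi))
        + 0.5 * v[:, 1] * (1.0 - np.cos(2.0 * phi))
        + 0.5 * v[:, 2] * (1.0 + np.cos(3.0 * phi))
    )


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Dihedral angle i-j-k-l in degrees on [0, 360)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x)) % 360.0


@dataclass
class EnergyDecomposition:
    """Potential energy split by REST region classes, kcal/mol.

    ``e_ss``: solute-solute (hot-region internal, including solute
    torsions); ``e_sw``: solute-environment; ``e_ww``:
    environment-environment.  ``total`` is their sum.
    """

    e_ss: float = 0.0
    e_sw: float = 0.0
    e_ww: float = 0.0

    @property
    def total(self) -> float:
        return self.e_ss + self.e_sw + self.e_ww

    def __add__(self, other: "EnergyDecomposition") -> "EnergyDecomposition":
        return EnergyDecomposition(
            self.e_ss + other.e_ss, self.e_sw + other.e_sw, self.e_ww + other.e_ww
        )

    def __sub__(self, other: "EnergyDecomposition") -> "EnergyDecomposition":
        return EnergyDecomposition(
            self.e_ss - other.e_ss, self.e_sw - other.e_sw, self.e_ww - other.e_ww
        )

    def __neg__(self) -> "EnergyDecomposition":
        return EnergyDecomposition(-self.e_ss, -self.e_sw, -self.e_ww)


@dataclass
class NonbondedParams:
    """Effective per-atom nonbonded and per-torsion parameters.

    Produced by :func:`interpolate`; also the container for a system's
    unperturbed parameters.  ``sc_shift`` is the per-atom soft-core
    separation shift (Angstrom^6) added to r^6 in the LJ evaluation;
    it is zero for all fully coupled atoms.
    """

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    sc_shift: np.ndarray
    torsion_v: np.ndarray  # (T, 3)

    def copy(self) -> "NonbondedParams":
        return NonbondedParams(
            self.charge.copy(),
            self.sigma.copy(),
            self.epsilon.copy(),
            self.sc_shift.copy(),
            self.torsion_v.copy(),
        )


class ToySystem:
    """A rigid-fragment molecular system with torsional degrees of freedom.

    Parameters
    ----------
    atoms : list of Atom
    rigid_fragments : list of lists of atom ids
        Must partition the atom ids.  Atoms in one fragment keep fixed
        relative geometry; rotatable bonds join fragments.
    torsions : list of TorsionTerm
    exclusions : iterable of 2-tuples
        1-2/1-3 atom pairs whose nonbonded interaction is omitted.
    pairs14 : iterable of 2-tuples
        1-4 pairs scaled by 0.5 (disjoint from exclusions).
    """

    def __init__(self, atoms, rigid_fragments, torsions, exclusions=(), pairs14=()):
        self.atoms = list(atoms)
        n = len(self.atoms)
        ids = sorted(a.id for a in self.atoms)
        if ids != list(range(n)):
            raise ValueError("atom ids must be dense 0..n-1")
        self.rigid_fragments = [sorted(f) for f in rigid_fragments]
        flat = sorted(i for f in self.rigid_fragments for i in f)
        if flat != list(range(n)):
            raise ValueError("rigid_fragments must partition the atom ids")
        self.torsions = list(torsions)
        self.exclusions = {frozenset(p) for p in exclusions}
        self.pairs14 = {frozenset(p) for p in pairs14}
        if self.exclusions & self.pairs14:
            raise ValueError("exclusions and 1-4 pairs must be disjoint")

        order = sorted(self.atoms, key=lambda a: a.id)
        self.positions = np.array([a.position for a in order], dtype=float)
        self.region = np.array([int(a.region) for a in order], dtype=np.int8)
        self.mobile = np.array([a.mobile for a in order], dtype=bool)
        self._base_params = NonbondedParams(
            charge=np.array([a.charge for a in order]),
            sigma=np.array([a.sigma for a in order]),
            epsilon=np.array([a.epsilon for a in order]),
            sc_shift=np.zeros(n),
            torsion_v=np.array([t.amplitudes for t in self.torsions]).reshape(-1, 3),
        )

        self._fragment_of = np.empty(n, dtype=int)
        for fi, frag in enumerate(self.rigid_fragments):
            for a in frag:
                self._fragment_of[a] = fi
        self._build_pair_table()
        self._moving_atoms = [self._moving_side(t) for t in self.torsions]
        for t, mov in zip(self.torsions, self._moving_atoms):
            if self._fragment_of[t.atom_ids[1]] == self._fragment_of[t.atom_ids[2]]:
                raise ValueError(
                    f"torsion bond {t.atom_ids[1]}-{t.atom_ids[2]} must join two "
                    "rigid fragments"
                )
            if not mov:
                raise ValueError("torsion has an empty moving side")

    # -- construction helpers -------------------------------------------------

    def _build_pair_table(self) -> None:
        n = len(self.atoms)
        iu, ju = np.triu_indices(n, k=1)
        keep = np.ones(iu.shape, dtype=bool)
        scale = np.ones(iu.shape)
        for idx in range(iu.size):
            pair = frozenset((int(iu[idx]), int(ju[idx])))
            if pair in self.exclusions:
                keep[idx] = False
            elif pair in self.pairs14:
                scale[idx] = SCALE_14
        self.pair_i = iu[keep]
        self.pair_j = ju[keep]
        self.pair_scale = scale[keep]

    def _moving_side(self, term: TorsionTerm) -> list[int]:
        """Atoms rotated when this torsion changes: fragments on the k/l
        side of the j-k bond, found on the fragment adjacency graph with
        the j-k edge removed."""
        j, k = term.atom_ids[1], term.atom_ids[2]
        fj, fk = int(self._fragment_of[j]), int(self._fragment_of[k])
        adj: dict[int, set[int]] = {}
        for t in self.torsions:
            a, b = int(self._fragment_of[t.atom_ids[1]]), int(
                self._fragment_of[t.atom_ids[2]]
            )
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        seen = {fk}
        stack = [fk]
        while stack:
            f = stack.pop()
            for g in adj.get(f, ()):
                if (f, g) in ((fj, fk), (fk, fj)):
                    continue
                if g not in seen:
                    seen.add(g)
                    stack.append(g)
        if fj in seen:
            raise ValueError("rotatable bonds must form a tree over fragments")
        return sorted(i for f in seen for i in self.rigid_fragments[f])

    # -- state ----------------------------------------------------------------

    def copy(self) -> "ToySystem":
        import copy as _copy

        new = _copy.copy(self)
        new.positions = self.positions.copy()
        return new

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def default_params(self) -> NonbondedParams:
        return self._base_params.copy()

    def solute_mask(self, hot_residue_scope: str = "full") -> np.ndarray:
        """Boolean mask of hot-region (REST solute) atoms.

        With ``hot_residue_scope='torsion_only'`` the hot residue's
        nonbonded interactions are classed as environment; only its
        torsion terms are tempered.
        """
        if hot_residue_scope == "full":
            return self.region != int(Region.ENVIRONMENT)
        if hot_residue_scope == "torsion_only":
            return self.region == int(Region.LIGAND)
        raise ValueError(f"unknown hot_residue_scope {hot_residue_scope!r}")

    def pair_classes(self, hot_residue_scope: str = "full") -> np.ndarray:
        """Decomposition class (ss/sw/ww) of every nonbonded pair."""
        sol = self.solute_mask(hot_residue_scope)
        a, b = sol[self.pair_i], sol[self.pair_j]
        cls = np.full(self.pair_i.shape, _SW, dtype=np.int8)
        cls[a & b] = _SS
        cls[~a & ~b] = _WW
        return cls

    def torsion_classes(self, hot_residue_scope: str = "full") -> np.ndarray:
        """Decomposition class of every torsion term.

        A torsion is classed by the majority region of its four atoms;
        on a tie it is solute-solute if any atom is in the hot region.
        Hot-residue torsions are always tempered (classed ss) even under
        ``torsion_only`` scope -- that scope narrows only the nonbonded
        scaling.
        """
        sol = self.region != int(Region.ENVIRONMENT)
        out = np.empty(len(self.torsions), dtype=np.int8)
        for t_idx, term in enumerate(self.torsions):
            n_sol = int(sol[list(term.atom_ids)].sum())
            # majority vote; the 2-2 tie goes to solute-solute
            out[t_idx] = _SS if n_sol >= 2 else _WW
        return out

    def torsion_angle(self, t_idx: int) -> float:
        i, j, k, l = self.torsions[t_idx].atom_ids
        p = self.positions
        return dihedral_angle(p[i], p[j], p[k], p[l])

    def torsion_angles(self) -> np.ndarray:
        return np.array([self.torsion_angle(t) for t in range(len(self.torsions))])

    def moving_atoms(self, t_idx: int) -> list[int]:
        return self._moving_atoms[t_idx]

    def set_torsion(self, t_idx: int, angle_deg: float) -> None:
        """Rotate the moving side about the j-k bond so the dihedral
        becomes ``angle_deg``."""
        delta = angle_deg - self.torsion_angle(t_idx)
        self.rotate_torsion(t_idx, delta)

    def rotate_torsion(self, t_idx: int, delta_deg: float) -> None:
        term = self.torsions[t_idx]
        j, k = term.atom_ids[1], term.atom_ids[2]
        axis_origin = self.positions[k]
        # axis k -> j so a positive rotation increases the dihedral
        axis = self.positions[j] - axis_origin
        mov = self._moving_atoms[t_idx]
        self.positions[mov] = _rotate_about_axis(
            self.positions[mov], axis_origin, axis, math.radians(delta_deg)
        )

    def region_atoms(self, region: Region) -> list[int]:
        return [int(i) for i in np.nonzero(self.region == int(region))[0]]


def _rotate_about_axis(points, origin, axis, angle_rad):
    """Rodrigues rotation of an (N,3) array about a line through origin."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    v = np.asarray(points, dtype=float) - origin
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    rotated = v * c + np.cross(k, v) * s + np.outer(v @ k, k) * (1.0 - c)
    return rotated + origin


# -- nonbonded ---------------------------------------------------------------


def nonbonded_pair_energy(a: Atom, b: Atom, scale14: float = 1.0) -> float:
    """LJ 12-6 + Coulomb energy of one atom pair, kcal/mol.

    Geometric combination rules for both sigma and epsilon (OPLS);
    ``scale14`` multiplies both terms (0.5 for 1-4 pairs).
    """
    r2 = float(np.sum((np.asarray(a.position) - np.asarray(b.position)) ** 2))
    if r2 == 0.0:
        raise OverlappingAtomsError(f"atoms {a.id} and {b.id} overlap")
    sig2 = a.sigma * b.sigma  # geometric: sigma_comb^2
    eps = math.sqrt(a.epsilon * b.epsilon)
    sr6 = (sig2 / r2) ** 3
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = COULOMB_CONSTANT * a.charge * b.charge / math.sqrt(r2)
    return scale14 * (lj + coul)


def _pair_energies(system: ToySystem, params: NonbondedParams) -> np.ndarray:
    """Energies of all non-excluded pairs, in pair-table order."""
    i, j = system.pair_i, system.pair_j
    d = system.positions[i] - system.positions[j]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 == 0.0):
        bad = int(np.nonzero(r2 == 0.0)[0][0])
        raise OverlappingAtomsError(f"atoms {i[bad]} and {j[bad]} overlap")
    sig6 = (params.sigma[i] * params.sigma[j]) ** 3
    eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
    r6 = r2 * r2 * r2 + params.sc_shift[i] + params.sc_shift[j]
    sr6 = sig6 / r6
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = COULOMB_CONSTANT * params.charge[i] * params.charge[j] / np.sqrt(r2)
    return system.pair_scale * (lj + coul)


def total_energy(
    system: ToySystem,
    params: NonbondedParams | None = None,
    hot_residue_scope: str = "full",
) -> EnergyDecomposition:
    """Region-decomposed total potential energy of the system."""
    if params is None:
        params = system._base_params
    out = [0.0, 0.0, 0.0]
    if system.pair_i.size:
        e_pairs = _pair_energies(system, params)
        cls = system.pair_classes(hot_residue_scope)
        for c in (_SS, _SW, _WW):
            out[c] += float(e_pairs[cls == c].sum())
    if system.torsions:
        e_tors = _torsion_energy_array(system.torsion_angles(), params.torsion_v)
        tcls = system.torsion_classes(hot_residue_scope)
        for c in (_SS, _SW, _WW):
            out[c] += float(e_tors[tcls == c].sum())
    return EnergyDecomposition(*out)


# -- alchemy -----------------------------------------------------------------


@dataclass(frozen=True)
class AtomEndpoints:
    """Endpoint nonbonded parameters for one mutated atom."""

    charge_a: float
    charge_b: float
    sigma_a: float
    sigma_b: float
    epsilon_a: float
    epsilon_b: float
    softcore: bool = False


@dataclass
class AlchemicalMap:
    """Single-topology mutation: endpoint parameters for the mutated
    atoms and torsions only.

    ``atoms`` maps atom id to :class:`AtomEndpoints`; ``torsions`` maps
    torsion index to a pair of Fourier amplitude triples (state A, state
    B).  The soft-core flag is forced on for any atom whose LJ well
    depth vanishes at either endpoint.
    """

    atoms: dict[int, AtomEndpoints] = field(default_factory=dict)
    torsions: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for aid, ep in list(self.atoms.items()):
            if (ep.epsilon_a == 0.0 or ep.epsilon_b == 0.0) and not ep.softcore:
                self.atoms[aid] = replace(ep, softcore=True)

    @property
    def is_empty(self) -> bool:
        return not self.atoms and not self.torsions

    def is_null(self) -> bool:
        """True when state A and state B are identical."""
        for ep in self.atoms.values():
            if (ep.charge_a, ep.sigma_a, ep.epsilon_a) != (
                ep.charge_b,
                ep.sigma_b,
                ep.epsilon_b,
            ):
                return False
        return all(va == vb for va, vb in self.torsions.values())

    def reversed(self) -> "AlchemicalMap":
        """The B -> A mutation."""
        return AlchemicalMap(
            atoms={
                aid: AtomEndpoints(
                    ep.charge_b, ep.charge_a, ep.sigma_b, ep.sigma_a,
                    ep.epsilon_b, ep.epsilon_a, ep.softcore,
                )
                for aid, ep in self.atoms.items()
            },
            torsions={t: (vb, va) for t, (va, vb) in self.torsions.items()},
        )


def interpolate(
    system: ToySystem, amap: AlchemicalMap, lam: float
) -> NonbondedParams:
    """Effective parameters at coupling parameter ``lam`` in [0, 1].

    Charges, LJ parameters and torsion amplitudes mix linearly; atoms
    flagged soft-core additionally acquire a separation shift
    ``alpha * sigma(lam)^6 * lam_v`` where ``lam_v`` is the distance in
    lambda from the fully coupled endpoint, so lambda = 0 and 1
    reproduce the pure endpoint Hamiltonians exactly.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    p = system.default_params()
    for aid, ep in amap.atoms.items():
        p.charge[aid] = (1.0 - lam) * ep.charge_a + lam * ep.charge_b
        p.sigma[aid] = (1.0 - lam) * ep.sigma_a + lam * ep.sigma_b
        p.epsilon[aid] = (1.0 - lam) * ep.epsilon_a + lam * ep.epsilon_b
        if ep.softcore:
            if ep.epsilon_a == 0.0 and ep.epsilon_b == 0.0:
                lam_v = 0.0
            elif ep.epsilon_a == 0.0:
                lam_v = 1.0 - lam  # atom grows in as lambda -> 1
            elif ep.epsilon_b == 0.0:
                lam_v = lam
            else:
                lam_v = min(lam, 1.0 - lam)  # manual flag: symmetric ramp
            p.sc_shift[aid] = SOFTCORE_ALPHA * p.sigma[aid] ** 6 * lam_v
    for t_idx, (va, vb) in amap.torsions.items():
        p.torsion_v[t_idx] = (1.0 - lam) * np.asarray(va) + lam * np.asarray(vb)
    return p
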