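"""Deterministic toy systems emulating a hydrophobic kinase pocket.

The pocket complex abstracts the geometry that makes fragment FEP hard:
a rigid cage of hydrophobic sites (the pocket), a three-site side-chain
rotor with a 3-fold torsion chi (the flexible pocket residue), and a
two-ring ligand whose rings are joined by a rotatable linker torsion
phi, carrying one mutable substituent at the meta position of the buried
ring.  Substituent identity changes only nonbonded parameters, so an
alchemical map between two substituents is a single-topology mutation.

The module also provides the isolated-rotor system and its quadrature
oracle: for a single torsion the partition function is a 1-D integral,
so exact free-energy differences and Boltzmann densities are available
to validate the samplers and estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0 as _bessel_i0

from .forcefield import (
    BOLTZMANN_KCAL,
    AlchemicalMap,
    Atom,
    AtomEndpoints,
    Region,
    TorsionTerm,
    ToySystem,
    torsion_energy,
)

__all__ = [
    "SubstituentCode",
    "SUBSTITUENTS",
    "PocketSpec",
    "RotorOracleResult",
    "make_rotor",
    "make_pocket_complex",
    "make_unbound_ligand",
    "substituent_map",
    "rotor_oracle",
    "boltzmann_density",
    "v1_closed_form_dg",
]


@dataclass(frozen=True)
class SubstituentCode:
    """Synthetic nonbonded parameters for one substituent identity.

    The labels follow the compound series (H, F, Cl, Br, CH3); the
    parameter values are this package's own OPLS-flavoured toy numbers,
    chosen so that sigma grows H < F < Cl < Br and the bulkier groups
    sterically couple to the pocket rotor.  They are fixture
    definitions, not measured force-field parameters.
    """

    label: str
    charge: float
    sigma: float
    epsilon: float


SUBSTITUENTS: dict[str, SubstituentCode] = {
    "H": SubstituentCode("H", +0.06, 2.42, 0.03),
    "F": SubstituentCode("F", -0.12, 2.94, 0.061),
    "CL": SubstituentCode("CL", -0.09, 3.40, 0.30),
    "BR": SubstituentCode("BR", -0.09, 3.47, 0.47),
    "CH3": SubstituentCode("CH3", 0.00, 3.50, 0.066),
}


@dataclass(frozen=True)
class PocketSpec:
    """Geometry and energetics of the generated pocket complex.

    Distances in Angstrom, energies in kcal/mol, angles in degrees.
    The torsion amplitudes shape the intrinsic phi/chi profiles; the
    nonbonded coupling between substituent, rotor and cage supplies the
    mode asymmetries.
    """

    n_cage_sites: int = 14
    cage_radius: float = 6.5
    cage_sigma: float = 3.5
    cage_epsilon: float = 0.12
    ring_radius: float = 1.4
    bond_length: float = 1.5
    ring_sigma: float = 3.3
    ring_epsilon: float = 0.08
    rotor_sigma: float = 3.2
    rotor_epsilon: float = 0.12
    rotor_tip_charge: float = 0.15
    rotor_bond: float = 1.53
    rotor_tilt1: float = 20.0
    rotor_tilt2: float = 70.0
    phi_amplitudes: tuple[float, float, float] = (0.4, 4.5, 0.0)
    chi_amplitudes: tuple[float, float, float] = (0.0, 0.0, 6.0)
    jitter: float = 0.12
    ligand_z: float = 2.2


@dataclass(frozen=True)
class RotorOracleResult:
    """Exact (quadrature) thermodynamics of a one-torsion system."""

    delta_g: float
    theta: np.ndarray  # degrees
    density_a: np.ndarray  # per degree, integrates to 1
    density_b: np.ndarray


def make_rotor(v1: float, v2: float, v3: float,
               initial_angle: float = 180.0) -> ToySystem:
    """A four-atom chain with a single mobile torsion and no nonbonded
    interactions -- the minimal system whose statistics are exactly
    computable by quadrature."""
    b = 1.5
    atoms = [
        Atom(0, (-b * math.cos(math.radians(70.5)), b * math.sin(math.radians(70.5)), 0.0),
             0.0, 3.0, 0.0, Region.LIGAND),
        Atom(1, (0.0, 0.0, 0.0), 0.0, 3.0, 0.0, Region.LIGAND),
        Atom(2, (b, 0.0, 0.0), 0.0, 3.0, 0.0, Region.LIGAND),
        Atom(3, (b + b * math.cos(math.radians(70.5)), b * math.sin(math.radians(70.5)), 0.0),
             0.0, 3.0, 0.0, Region.LIGAND),
    ]
    all_pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    system = ToySystem(
        atoms=atoms,
        rigid_fragments=[[0, 1], [2, 3]],
        torsions=[TorsionTerm((0, 1, 2, 3), v1, v2, v3)],
        exclusions=all_pairs,
    )
    system.set_torsion(0, initial_angle)
    return system


def _hemisphere_sites(n: int, radius: float, rng: np.random.Generator,
                      jitter: float) -> np.ndarray:
    """Deterministic Fibonacci-spiral sites on the lower hemisphere,
    with a small seeded jitter so distinct seeds give distinct pockets."""
    k = np.arange(n)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    # z from just below the equator down to the pole
    z = -0.25 - 0.75 * (k + 0.5) / n
    r_xy = np.sqrt(1.0 - z**2)
    phi = golden * k
    sites = radius * np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return sites + rng.normal(scale=jitter, size=sites.shape)


def make_pocket_complex(
    spec: PocketSpec = PocketSpec(),
    substituent: SubstituentCode | str = "F",
    seed: int = 0,
    max_retries: int = 5,
) -> ToySystem:
    """Build the pocket complex: cage + side-chain rotor + two-ring
    ligand with one substituent site.

    Atom layout (ids): ring A 0-5, ring B 6-11, substituent 12, rotor
    13-15, cage 16 .. 15+n_cage_sites.  Ligand atoms come first so the
    unbound-ligand subsystem shares atom ids and alchemical maps with
    the complex.  Construction is deterministic for a given
    (spec, seed); if the jittered cage overlaps another atom the build
    retries with a derived sub-seed a bounded number of times.
    """
    if isinstance(substituent, str):
        substituent = SUBSTITUENTS[substituent.upper()]
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt, 20170802])
        system = _build_pocket(spec, substituent, rng)
        d = system.positions[:, None, :] - system.positions[None, :, :]
        dist = np.sqrt((d**2).sum(axis=2)) + np.eye(system.n_atoms) * 99.0
        if dist.min() > 0.9:
            return system
    raise RuntimeError("could not generate a non-overlapping pocket")


def _build_pocket(spec: PocketSpec, sub: SubstituentCode,
                  rng: np.random.Generator) -> ToySystem:
    rr, bl = spec.ring_radius, spec.bond_length
    # Biphenyl-like ligand along the z axis: both ring planes contain
    # the A0-B0 linker bond, so rotating phi swings ring B's plane (and
    # with it the meta substituent) around the pocket axis.  Ring B is
    # buried; ring A sits above the pocket mouth.
    zb = spec.ligand_z  # z of ring B center
    b_center = np.array([0.0, 0.0, zb])

    def _ring_xz(center: np.ndarray, top_angle_deg: float) -> np.ndarray:
        ts = np.radians(top_angle_deg - 60.0 * np.arange(6))
        return center + rr * np.stack(
            [np.sin(ts), np.zeros(6), np.cos(ts)], axis=1
        )

    ring_b = _ring_xz(b_center, 0.0)  # B0 at the top vertex
    b0 = ring_b[0]
    a0 = b0 + np.array([0.0, 0.0, bl])
    a_center = a0 + np.array([0.0, 0.0, rr])
    ring_a = _ring_xz(a_center, 180.0)  # A0 at the bottom vertex
    # substituent at the meta position of ring B, radially outward
    sub_dir = ring_b[2] - b_center
    sub_pos = ring_b[2] + sub_dir / np.linalg.norm(sub_dir) * bl

    cage = _hemisphere_sites(spec.n_cage_sites, spec.cage_radius, rng, spec.jitter)
    # rotor anchored at the rim cage site nearest the +x direction
    anchor_idx = int(np.argmax(cage[:, 0]))
    anchor = cage[anchor_idx]
    out = -anchor / np.linalg.norm(anchor)  # points into the pocket
    # The anchor->r0 bond is tilted off the inward axis (so the chi
    # dihedral is well defined) while r0->r1 runs straight into the
    # pocket: r2 then sweeps a cone of half-angle rotor_tilt2 about the
    # inward axis as chi rotates.
    tilt = np.array([0.0, 0.0, 1.0]) - out * out[2]
    tilt = tilt / np.linalg.norm(tilt)
    t1, t2 = math.radians(spec.rotor_tilt1), math.radians(spec.rotor_tilt2)
    d0 = out * math.cos(t1) - tilt * math.sin(t1)
    r0 = anchor + d0 * spec.rotor_bond
    r1 = r0 + out * spec.rotor_bond
    d2 = out * math.cos(t2) + tilt * math.sin(t2)
    r2 = r1 + d2 * spec.rotor_bond

    atoms: list[Atom] = []
    idx = 0
    for p in ring_a:
        atoms.append(Atom(idx, tuple(p), 0.0, spec.ring_sigma, spec.ring_epsilon,
                          Region.LIGAND))
        idx += 1
    for p in ring_b:
        atoms.append(Atom(idx, tuple(p), 0.0, spec.ring_sigma, spec.ring_epsilon,
                          Region.LIGAND))
        idx += 1
    atoms.append(Atom(idx, tuple(sub_pos), sub.charge, sub.sigma, sub.epsilon,
                      Region.LIGAND))
    sub_id = idx
    idx += 1
    # the rotor tip carries a small positive charge so halogenated
    # substituents feel a rotamer-dependent electrostatic contact
    for p, q in ((r0, 0.0), (r1, 0.0), (r2, spec.rotor_tip_charge)):
        atoms.append(Atom(idx, tuple(p), q, spec.rotor_sigma, spec.rotor_epsilon,
                          Region.HOT_RESIDUE))
        idx += 1
    cage_start = idx
    for ci, p in enumerate(cage):
        atoms.append(Atom(idx, tuple(p), 0.0, spec.cage_sigma, spec.cage_epsilon,
                          Region.ENVIRONMENT, mobile=False))
        idx += 1

    r0_id, r1_id, r2_id = sub_id + 1, sub_id + 2, sub_id + 3
    anchor_id = cage_start + anchor_idx

    bonds = []
    for ring_start in (0, 6):
        for i in range(6):
            bonds.append((ring_start + i, ring_start + (i + 1) % 6))
    bonds += [(0, 6), (8, sub_id), (anchor_id, r0_id), (r0_id, r1_id),
              (r1_id, r2_id)]

    excl, p14 = _bonded_neighbourhoods(len(atoms), bonds)

    torsions = [
        TorsionTerm((1, 0, 6, 7), *spec.phi_amplitudes),       # phi (linker)
        TorsionTerm((anchor_id, r0_id, r1_id, r2_id), *spec.chi_amplitudes),  # chi
    ]
    fragments = (
        [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11, sub_id], [r0_id], [r1_id, r2_id]]
        + [[cage_start + i] for i in range(spec.n_cage_sites)]
    )
    system = ToySystem(atoms, fragments, torsions, exclusions=excl, pairs14=p14)
    system.set_torsion(0, 180.0)
    system.set_torsion(1, 180.0)
    return system


def _cyclic_order(ring: np.ndarray) -> np.ndarray:
    """Order six coplanar hexagon sites into a cycle starting from the
    current first row."""
    center = ring.mean(axis=0)
    n = np.cross(ring[1] - ring[0], ring[2] - ring[0])
    n /= np.linalg.norm(n)
    u = ring[0] - center
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ang = np.arctan2((ring - center) @ v, (ring - center) @ u)
    return ring[np.argsort(ang % (2 * math.pi))]


def _bonded_neighbourhoods(n_atoms: int, bonds: list[tuple[int, int]]):
    """1-2/1-3 exclusions and 1-4 scaled pairs from the bond graph."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    excl, p14 = set(), set()
    for start in range(n_atoms):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                if dist[u] >= 3:
                    continue
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for w, d in dist.items():
            if w <= start:
                continue
            if d <= 2:
                excl.add((start, w))
            elif d == 3:
                p14.add((start, w))
    return excl, p14


def make_unbound_ligand(
    spec: PocketSpec = PocketSpec(),
    substituent: SubstituentCode | str = "F",
    seed: int = 0,
) -> ToySystem:
    """The ligand alone (rings + substituent) with the same atom ids and
    internal interactions as in the complex -- the unbound leg of the
    thermodynamic cycle, in vacuum."""
    complex_system = make_pocket_complex(spec, substituent, seed)
    keep = complex_system.region_atoms(Region.LIGAND)
    keep_set = set(keep)
    atoms = [complex_system.atoms[i] for i in keep]
    fragments = [
        [a for a in frag if a in keep_set]
        for frag in complex_system.rigid_fragments
    ]
    fragments = [f for f in fragments if f]
    torsions = [
        t for t in complex_system.torsions if set(t.atom_ids) <= keep_set
    ]
    excl = {p for p in complex_system.exclusions if p <= keep_set}
    p14 = {p for p in complex_system.pairs14 if p <= keep_set}
    return ToySystem(atoms, fragments, torsions,
                     exclusions=[tuple(p) for p in excl],
                     pairs14=[tuple(p) for p in p14])


def substituent_map(system: ToySystem, a: SubstituentCode | str,
                    b: SubstituentCode | str,
                    substituent_atom: int = 12) -> AlchemicalMap:
    """Single-topology mutation of the substituent site from identity
    ``a`` to identity ``b``."""
    if isinstance(a, str):
        a = SUBSTITUENTS[a.upper()]
    if isinstance(b, str):
        b = SUBSTITUENTS[b.upper()]
    return AlchemicalMap(
        atoms={
            substituent_atom: AtomEndpoints(
                charge_a=a.charge, charge_b=b.charge,
                sigma_a=a.sigma, sigma_b=b.sigma,
                epsilon_a=a.epsilon, epsilon_b=b.epsilon,
            )
        }
    )


# -- quadrature oracles ------------------------------------------------------


def boltzmann_density(amplitudes: tuple[float, float, float],
                      temperature: float,
                      grid_step: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Normalised Boltzmann density (per degree) of one OPLS torsion on
    a uniform grid over [0, 360)."""
    theta = np.arange(0.0, 360.0, grid_step)
    term = TorsionTerm((0, 1, 2, 3), *amplitudes)
    v = np.array([torsion_energy(t, term) for t in theta])
    w = np.exp(-(v - v.min()) / (BOLTZMANN_KCAL * temperature))
    z = np.trapezoid(np.append(w, w[0]), dx=grid_step)  # periodic closure
    return theta, w / z


def rotor_oracle(
    v_a: tuple[float, float, float],
    v_b: tuple[float, float, float],
    temperature: float = 298.15,
    grid_step: float = 0.1,
) -> RotorOracleResult:
    """Exact free-energy difference dG = -kT ln(Z_B/Z_A) for a torsion
    whose Fourier amplitudes mutate from ``v_a`` to ``v_b``, by
    trapezoidal quadrature on a fine periodic grid, together with both
    endpoint Boltzmann densities."""
    kt = BOLTZMANN_KCAL * temperature
    theta = np.arange(0.0, 360.0, grid_step)
    term_a = TorsionTerm((0, 1, 2, 3), *v_a)
    term_b = TorsionTerm((0, 1, 2, 3), *v_b)
    va = np.array([torsion_energy(t, term_a) for t in theta])
    vb = np.array([torsion_energy(t, term_b) for t in theta])
    ref = min(va.min(), vb.min())
    wa = np.exp(-(va - ref) / kt)
    wb = np.exp(-(vb - ref) / kt)
    za = np.trapezoid(np.append(wa, wa[0]), dx=grid_step)
    zb = np.trapezoid(np.append(wb, wb[0]), dx=grid_step)
    return RotorOracleResult(
        delta_g=float(-kt * math.log(zb / za)),
        theta=theta,
        density_a=wa / za,
        density_b=wb / zb,
    )


def v1_closed_form_dg(v1: float, temperature: float = 298.15) -> float:
    """Closed-form dG for switching a flat torsion to a V1-only torsion:
    dG = V1/2 - kT ln I0(V1 / 2kT), with I0 the modified Bessel
    function -- an independent check on the quadrature oracle."""
    kt = BOLTZMANN_KCAL * temperature
    return 0.5 * v1 - kt * math.log(float(_bessel_i0(0.5 * v1 / kt)))
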