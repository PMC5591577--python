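"""Binding-mode and benchmarking analytics.

Dihedral histograms summarise the torsional ensembles that distinguish
binding modes; mode populations and the symmetric-mode entropy
-T dS = -kT sum p ln p quantify the free-energy cost of losing
equivalent orientations.  The benchmark utilities convert measured
IC50 values to a relative free-energy scale via RT ln(IC50), align
computed and experimental distributions to a common mean, and report
the standard error statistics (MUE, RMSE, Pearson r) used to judge
congeneric-series predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .forcefield import BOLTZMANN_KCAL
from .sampler import Trajectory

__all__ = [
    "DihedralHistogram",
    "ModeAssignment",
    "BenchmarkRecord",
    "BenchmarkStats",
    "dihedral_histogram",
    "mode_populations_entropy",
    "experimental_dg",
    "benchmark_stats",
    "starting_structure_consistency",
    "load_benchmark_csv",
    "load_reference_table",
    "DEFAULT_MODE_CENTERS",
]

#: Default binding-mode centers (degrees): ligand linker phi and
#: side-chain rotamer chi.
DEFAULT_MODE_CENTERS = {"phi": (180.0, 330.0), "chi": (60.0, 180.0)}


@dataclass
class DihedralHistogram:
    """Circular histogram of one torsion over [0, 360)."""

    torsion_id: int
    edges: np.ndarray  # len n_bins + 1, tiling [0, 360]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("bin fractions must sum to 1")


def dihedral_histogram(
    traj: Trajectory, torsion_id: int, bin_width: float = 10.0
) -> DihedralHistogram:
    """Histogram the recorded angles of one torsion with circular bins
    of ``bin_width`` degrees (which must tile 360)."""
    if torsion_id not in traj.torsion_ids:
        raise ValueError(f"torsion {torsion_id} not recorded in trajectory")
    n_bins = round(360.0 / bin_width)
    if abs(n_bins * bin_width - 360.0) > 1e-9:
        raise ValueError("bin_width must divide 360")
    angles = traj.angle(torsion_id) % 360.0
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))
    return DihedralHistogram(
        torsion_id=torsion_id,
        edges=edges,
        fractions=counts / counts.sum(),
    )


def circular_distance(a, b):
    """Shortest angular distance in degrees."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass
class ModeAssignment:
    """Frames assigned to discrete binding modes by nearest center."""

    centers: tuple[float, ...]
    populations: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("mode populations must sum to 1")


def mode_populations_entropy(
    angles,
    mode_centers,
    temperature: float = 298.15,
) -> tuple[ModeAssignment, float]:
    """Assign angles to modes and return the entropic term T dS.

    Each angle goes to the nearest mode center on the circle (ties to
    the lower-indexed center).  T dS = -T k sum p ln p in kcal/mol is
    the free-energy credit of populating several modes, relative to a
    single-mode reference; it is maximal, kT ln M, for M equally
    populated modes.
    """
    angles = np.asarray(angles, dtype=float)
    centers = tuple(float(c) for c in mode_centers)
    if angles.size == 0:
        raise ValueError("no angles to assign")
    if len(centers) == 0:
        raise ValueError("at least one mode center required")
    d = circular_distance(angles[:, None], np.array(centers)[None, :])
    assign = np.argmin(d, axis=1)  # argmin takes the first (lowest) index on ties
    pops = np.bincount(assign, minlength=len(centers)) / angles.size
    p = pops[pops > 0]
    tds = float(-BOLTZMANN_KCAL * temperature * np.sum(p * np.log(p)))
    return ModeAssignment(centers=centers, populations=pops), tds


def experimental_dg(ic50_uM: float, temperature: float = 298.15) -> float:
    """Relative experimental binding free energy RT ln(IC50/uM), kcal/mol.

    Absolute scale is arbitrary (1 uM maps to 0); only differences are
    meaningful, and the benchmark's mean-offset step removes the
    constant anyway.
    """
    if not ic50_uM > 0:
        raise ValueError("IC50 must be positive")
    return BOLTZMANN_KCAL * temperature * math.log(ic50_uM)


@dataclass
class BenchmarkRecord:
    """One compound of the congeneric series."""

    compound: str
    ddg: float | None  # computed relative binding free energy, kcal/mol
    ic50_uM: float | None = None
    ki_uM: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_uM is not None and not self.ic50_uM > 0:
            raise ValueError(f"compound {self.compound}: IC50 must be > 0")

    @property
    def complete(self) -> bool:
        return self.ddg is not None and self.ic50_uM is not None

    def experimental_dg(self, temperature: float = 298.15) -> float | None:
        if self.ic50_uM is None:
            return None
        return experimental_dg(self.ic50_uM, temperature)


@dataclass
class BenchmarkStats:
    """Offset-aligned error statistics of computed vs experimental."""

    n: int
    offset: float
    mue: float
    rmse: float
    pearson_r: float


def benchmark_stats(
    records: list[BenchmarkRecord], temperature: float = 298.15
) -> BenchmarkStats:
    """MUE, RMSE and Pearson r between computed ddG and RT ln(IC50),
    after shifting the computed values to the experimental mean.

    Only records with both a computed value and a measured IC50 enter;
    at least two are required.  All three statistics are invariant to
    adding a constant to every computed value.
    """
    comp = np.array([r.ddg for r in records if r.complete], dtype=float)
    exp = np.array(
        [r.experimental_dg(temperature) for r in records if r.complete], dtype=float
    )
    if comp.size < 2:
        raise ValueError("need at least two complete records")
    offset = float(exp.mean() - comp.mean())
    diff = comp + offset - exp
    return BenchmarkStats(
        n=int(comp.size),
        offset=offset,
        mue=float(np.abs(diff).mean()),
        rmse=float(np.sqrt((diff**2).mean())),
        pearson_r=float(np.corrcoef(comp, exp)[0, 1]),
    )


def starting_structure_consistency(
    totals, tol_kcal: float | None = None, stderrs=None
) -> tuple[bool, float]:
    """Check that repeat free-energy estimates from different starting
    conformations agree.

    Returns (passed, max pairwise spread).  With ``tol_kcal`` omitted,
    the tolerance defaults to three times the combined standard error
    of the least precise pair (which requires ``stderrs``).
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size < 2:
        raise ValueError("need at least two repeat results")
    spread = float(totals.max() - totals.min())
    if tol_kcal is None:
        if stderrs is None:
            raise ValueError("give tol_kcal or stderrs")
        errs = np.sort(np.asarray(stderrs, dtype=float))[::-1]
        tol_kcal = 3.0 * math.hypot(errs[0], errs[1])
    return spread <= tol_kcal, spread


def load_benchmark_csv(path) -> list[BenchmarkRecord]:
    """Read a benchmark table (columns: compound, ddg_kcal, ic50_uM,
    ki_uM; blank cells for unmeasured values)."""
    df = pd.read_csv(path, dtype={"compound": str})
    required = {"compound", "ddg_kcal", "ic50_uM"}
    if not required <= set(df.columns):
        raise ValueError(f"benchmark CSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BenchmarkRecord(
                compound=str(row.compound),
                ddg=None if pd.isna(row.ddg_kcal) else float(row.ddg_kcal),
                ic50_uM=None if pd.isna(row.ic50_uM) else float(row.ic50_uM),
                ki_uM=(
                    None
                    if "ki_uM" not in df.columns or pd.isna(row.ki_uM)
                    else float(row.ki_uM)
                ),
            )
        )
    return records


def load_reference_table() -> list[BenchmarkRecord]:
    """The packaged congeneric-series table: published computed ddG
    (kcal/mol) with assay IC50 and Ki (uM) where measured."""
    with resources.as_file(
        resources.files("restfep.data").joinpath("aurora_series.csv")
    ) as p:
        return load_benchmark_csv(p)
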