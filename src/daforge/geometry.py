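"""3D structure generation and geometric analysis of cycloadducts.

Covers the conformer-embedding stage of the workflow (distance-geometry
embedding followed by UFF relaxation, with a bounded retry escalation),
the construction of the constrained two-fragment pseudo-guess
specification, the synchronicity index of a transition-state geometry,
and plain-text XYZ I/O.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "Geometry",
    "ConstraintSpec",
    "EmbedParams",
    "EmbeddingFailure",
    "embed_with_retry",
    "build_pseudo_guess_constraints",
    "synchronicity_index",
    "read_xyz",
    "write_xyz",
]

#: Valid provenance tags for a Geometry record.
PROVENANCES = (
    "embedded",
    "ff_optimized",
    "scan_point",
    "guess_ts",
    "refined_ts",
    "irc_point",
)

#: Default forming-bond separation (Angstrom) of the pseudo-guess.
DEFAULT_SEPARATION_A = 2.15

#: Two-stage retry escalation: (n_conformers, max_iters) per attempt.
#: Bounded by the documented caps of 60 conformers and 2000 iterations.
ESCALATION_SCHEDULE = ((10, 200), (60, 2000))


class EmbeddingFailure(RuntimeError):
    """Raised when every embedding attempt in the schedule fails."""


@dataclasses.dataclass
class Geometry:
    """A molecular geometry: element symbols plus Cartesian coordinates in Angstrom."""

    elements: list[str]
    coords: np.ndarray  # (N, 3), Angstrom
    charge: int = 0
    multiplicity: int = 1
    provenance: str = "embedded"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("element list length must equal coordinate count")
        if self.coords.shape[0] < 1:
            raise ValueError("geometry must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def distance(self, i: int, j: int) -> float:
        """Euclidean distance between atoms i and j in Angstrom."""
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def copy(self) -> "Geometry":
        return Geometry(
            list(self.elements),
            self.coords.copy(),
            self.charge,
            self.multiplicity,
            self.provenance,
        )


@dataclasses.dataclass(frozen=True)
class DistanceConstraint:
    atom_i: int
    atom_j: int
    target_A: float
    frozen: bool = True


@dataclasses.dataclass
class ConstraintSpec:
    """Distance constraints imposed during the pseudo-guess optimization.

    For a standard Diels-Alder pseudo-guess there are exactly two, on the
    forming C-C bonds (d1, e1) and (d4, e2).
    """

    distance_constraints: list[DistanceConstraint]

    def __post_init__(self) -> None:
        for c in self.distance_constraints:
            if c.target_A <= 0:
                raise ValueError(f"constraint target must be positive, got {c.target_A}")


@dataclasses.dataclass(frozen=True)
class EmbedParams:
    """Parameters for one embedding attempt; escalation stays within the caps."""

    n_conformers: int = 10
    max_iters: int = 200
    random_seed: int = 42

    def __post_init__(self) -> None:
        if not (1 <= self.n_conformers <= 60):
            raise ValueError("n_conformers must lie in [1, 60]")
        if not (1 <= self.max_iters <= 2000):
            raise ValueError("max_iters must lie in [1, 2000]")


def _try_embed(mol: Chem.Mol, n_conformers: int, max_iters: int, seed: int):
    """One embedding attempt: multi-conformer ETKDG + UFF relaxation.

    Returns (conformer_id, energy) of the lowest-energy converged
    conformer, or None on failure.  Separated out so tests can exercise
    the escalation path.
    """
    work = Chem.Mol(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    conf_ids = AllChem.EmbedMultipleConfs(work, numConfs=n_conformers, params=params)
    if len(conf_ids) == 0:
        return None
    results = AllChem.UFFOptimizeMoleculeConfs(work, maxIters=max_iters)
    best = None
    for cid, (not_converged, energy) in zip(conf_ids, results):
        if not_converged:
            continue
        if best is None or energy < best[1]:
            best = (cid, energy, work)
    return best


def embed_with_retry(adduct, params: EmbedParams | None = None) -> Geometry:
    """Embed a cycloadduct in 3D and relax it with the UFF force field.

    The lowest-energy converged conformer is returned.  On failure the
    attempt is repeated with more conformers and more minimizer
    iterations, up to the documented caps (60 conformers, 2000 runs).
    UFF is non-reactive, so the bond graph of the result is the input
    graph by construction.

    Parameters
    ----------
    adduct : Cycloadduct
        Parsed cycloadduct record (``retro_da.Cycloadduct``).
    params : EmbedParams, optional
        First-attempt parameters; escalation then jumps to the caps.

    Raises
    ------
    EmbeddingFailure
        If every attempt in the schedule fails.
    """
    if params is None:
        params = EmbedParams()
    mol = Chem.AddHs(Chem.Mol(adduct.mol))
    schedule = [(params.n_conformers, params.max_iters)]
    for n_conf, max_it in ESCALATION_SCHEDULE[1:]:
        if (n_conf, max_it) not in schedule and n_conf >= params.n_conformers:
            schedule.append((n_conf, max_it))
    last_error = None
    for attempt, (n_conf, max_it) in enumerate(schedule, start=1):
        try:
            best = _try_embed(mol, n_conf, max_it, params.random_seed)
        except Exception as exc:  # embedding can raise inside RDKit
            best = None
            last_error = exc
        if best is not None:
            cid, _energy, work = best
            conf = work.GetConformer(cid)
            coords = np.array(conf.GetPositions(), dtype=float)
            elements = [a.GetSymbol() for a in work.GetAtoms()]
            geom = Geometry(
                elements,
                coords,
                charge=Chem.GetFormalCharge(work),
                provenance="ff_optimized",
            )
            geom.attempts = attempt  # type: ignore[attr-defined]
            return geom
    raise EmbeddingFailure(
        f"embedding failed after {len(schedule)} attempts"
        + (f" (last error: {last_error})" if last_error else "")
    )


def build_pseudo_guess_constraints(site, separation_A: float = DEFAULT_SEPARATION_A) -> ConstraintSpec:
    """Constraints coercing the adduct into the symmetric two-fragment pseudo-guess.

    The two pairs of terminal carbons of the forming bonds, (d1, e1) and
    (d4, e2), are each held at ``separation_A`` (default 2.15 Angstrom;
    user-configurable).
    """
    if separation_A <= 0:
        raise ValueError(f"separation must be positive, got {separation_A}")
    d1, _, _, d4 = site.diene_atoms
    e1, e2 = site.dienophile_atoms
    return ConstraintSpec(
        [
            DistanceConstraint(d1, e1, separation_A),
            DistanceConstraint(d4, e2, separation_A),
        ]
    )


def synchronicity_index(ts_geom: Geometry, site) -> float:
    """Synchronicity index S of a transition-state geometry.

    S is the absolute difference of the two forming C-C bond lengths at
    the TS, in Angstrom.  Synchronous reactions have S close to zero;
    asynchronous ones have larger values.
    """
    d1, _, _, d4 = site.diene_atoms
    e1, e2 = site.dienophile_atoms
    n = ts_geom.n_atoms
    for idx in (d1, d4, e1, e2):
        if not (0 <= idx < n):
            raise IndexError(f"atom index {idx} out of range for {n}-atom geometry")
    return abs(ts_geom.distance(d1, e1) - ts_geom.distance(d4, e2))


def write_xyz(geom: Geometry, path, comment: str = "") -> Path:
    """Write a geometry in standard XYZ format (coordinates to 6 decimals)."""
    path = Path(path)
    lines = [str(geom.n_atoms), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(geom.elements, geom.coords):
        lines.append(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_xyz(path) -> Geometry:
    """Read a standard XYZ file into a Geometry."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    n = int(lines[0].strip())
    if len(lines) < n + 2:
        raise ValueError(f"truncated XYZ file: {path}")
    elements: list[str] = []
    coords = np.zeros((n, 3))
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        elements.append(parts[0])
        coords[i] = [float(v) for v in parts[1:4]]
    return Geometry(elements, coords)


def set_distance(coords: np.ndarray, i: int, j: int, target_A: float) -> np.ndarray:
    """Return coords with atom ``j`` moved along the i->j axis to distance ``target_A``."""
    coords = np.array(coords, dtype=float)
    vec = coords[j] - coords[i]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        vec = np.array([1.0, 0.0, 0.0])
        norm = 1.0
    coords[j] = coords[i] + vec / norm * target_A
    return coords
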