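"""Atomic decomposition of the reaction force and force constant.

The total reaction force can be rewritten with the Hellmann-Feynman
forces F_A acting on each nucleus A:

    F(xi) = -dE/dxi = sum_A F_A . (dR_A/dxi) = sum_A F_A(xi)

and differentiating once more gives per-atom force-constant
contributions kappa_A with sum_A kappa_A = kappa.  When Cartesian
Hessians H(xi) are available along the path, kappa further splits into a
diagonal "atoms" part and an off-diagonal pairwise "bonds" part:

    kappa_AB = t_A^T H_AB t_B                      (A != B)
    kappa_AA = t_A^T H_AA t_A - F_A . (d2R_A/dxi2)
    kappa    = sum_A kappa_AA + 2 sum_{A<B} kappa_AB
             = kappa_atoms + kappa_bonds

with t_A = dR_A/dxi the per-atom path tangent.  All tangents are
computed with the same averaged forward/backward difference scheme used
for the total profiles, so the decomposition identities hold to the
scheme's truncation error on consistent inputs.

Coordinates enter in Angstrom and are converted to bohr internally so
that forces (Hartree/bohr) and Hessians (Hartree/bohr^2) combine into
contributions in Hartree/xi and Hartree/xi^2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .rfa import IRCPath, finite_difference, rfa_profile
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "DecompositionProfile",
    "HessianSeries",
    "CapabilityError",
    "StructureError",
    "path_tangents",
    "atomic_force_decomposition",
    "atomic_kappa_decomposition",
    "atoms_bonds_split",
    "fragment_aggregate",
    "write_decomposition_table",
]


class CapabilityError(RuntimeError):
    """The path lacks the data (forces, Hessians) this analysis needs."""


class StructureError(RuntimeError):
    """Inconsistent structure across path points."""


@dataclasses.dataclass
class HessianSeries:
    """Per-point Cartesian Hessians, each (3N, 3N), in Hartree/bohr^2."""

    hessians: np.ndarray  # (P, 3N, 3N)

    def __post_init__(self) -> None:
        self.hessians = np.asarray(self.hessians, dtype=float)
        if self.hessians.ndim != 3 or self.hessians.shape[1] != self.hessians.shape[2]:
            raise ValueError("hessians must have shape (P, 3N, 3N)")
        if not np.allclose(self.hessians, np.swapaxes(self.hessians, 1, 2), atol=1e-10):
            raise ValueError("each Hessian must be symmetric")

    @property
    def n_points(self) -> int:
        return self.hessians.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.hessians.shape[1] // 3


@dataclasses.dataclass
class DecompositionProfile:
    """Per-atom and atoms/bonds decomposition curves along an IRC path."""

    xi: np.ndarray
    atom_force: np.ndarray | None = None  # (P, N): F_A(xi)
    atom_kappa: np.ndarray | None = None  # (P, N): kappa_A(xi)
    kappa_AA: np.ndarray | None = None  # (P, N)
    kappa_AB: np.ndarray | None = None  # (P, N, N), zero diagonal, symmetric
    kappa_atoms: np.ndarray | None = None  # (P,)
    kappa_bonds: np.ndarray | None = None  # (P,)
    fragments: dict[str, np.ndarray] | None = None  # name -> aggregated kappa_A curve
    units_note: str = (
        "xi: amu^(1/2)*bohr; F_A: Hartree/xi; kappa curves: Hartree/xi^2 "
        "(Cartesian inputs converted Angstrom->bohr)"
    )


def path_tangents(path: IRCPath) -> np.ndarray:
    """Per-atom path tangents dR_A/dxi, shape (P, N, 3), in bohr per xi unit."""
    coords = path.coords_array() * ANGSTROM_TO_BOHR
    if any(g.n_atoms != path.n_atoms for g in path.geometries):
        raise StructureError("atom count varies along the path")
    return finite_difference(coords, path.xi)


def atomic_force_decomposition(path: IRCPath) -> DecompositionProfile:
    """Project the Hellmann-Feynman forces onto the path tangents.

    atom_force[i, A] = F_A(xi_i) . (dR_A/dxi)(xi_i); the sum over atoms
    reproduces the total reaction force within truncation tolerance.
    """
    if not path.has_forces:
        raise CapabilityError("path carries no per-atom forces; decomposition unavailable")
    tangents = path_tangents(path)
    atom_force = np.einsum("pax,pax->pa", path.forces, tangents)
    return DecompositionProfile(xi=path.xi.copy(), atom_force=atom_force)


def atomic_kappa_decomposition(profile: DecompositionProfile, path: IRCPath) -> DecompositionProfile:
    """Per-atom force-constant contributions kappa_A = -d(F_A)/dxi."""
    if profile.atom_force is None:
        raise ValueError("compute the atomic force decomposition first")
    profile.atom_kappa = -finite_difference(profile.atom_force, path.xi)
    return profile


def atoms_bonds_split(
    path: IRCPath,
    hessians: HessianSeries,
    profile: DecompositionProfile | None = None,
) -> DecompositionProfile:
    """Split kappa into diagonal (atoms) and pairwise (bonds) components.

    Requires per-point Cartesian Hessians.  Endpoint values use
    one-sided tangents and second derivatives and should be read with
    the corresponding truncation caveat; reports exclude them.
    """
    if hessians.n_points != path.n_points:
        raise CapabilityError("Hessian series length does not match the path")
    if hessians.n_atoms != path.n_atoms:
        raise CapabilityError("Hessian dimension does not match the atom count")
    if not path.has_forces:
        raise CapabilityError("atoms/bonds split needs per-atom forces for the kappa_AA term")
    if profile is None:
        profile = atomic_force_decomposition(path)
    P, N = path.n_points, path.n_atoms
    t = path_tangents(path)  # (P, N, 3)
    accel = finite_difference(t, path.xi)  # d2R_A/dxi2, (P, N, 3)
    H = hessians.hessians.reshape(P, N, 3, N, 3)
    # kappa_pair[p, A, B] = t_A^T H_AB t_B
    kappa_pair = np.einsum("pax,paxby,pby->pab", t, H, t)
    kappa_AA = np.einsum("paa->pa", kappa_pair) - np.einsum("pax,pax->pa", path.forces, accel)
    kappa_AB = kappa_pair.copy()
    idx = np.arange(N)
    kappa_AB[:, idx, idx] = 0.0
    profile.kappa_AA = kappa_AA
    profile.kappa_AB = kappa_AB
    profile.kappa_atoms = kappa_AA.sum(axis=1)
    profile.kappa_bonds = kappa_AB.sum(axis=(1, 2))  # = 2 * sum_{A<B}
    return profile


def fragment_aggregate(
    profile: DecompositionProfile, fragments: dict[str, tuple[int, ...]]
) -> DecompositionProfile:
    """Aggregate per-atom curves over named, disjoint atom groups.

    Typical use: the two forming-bond pairs {d1, e1} and {d4, e2} of a
    Diels-Alder site, whose kappa_A curves expose which C-C bond forms
    first in asynchronous reactions.
    """
    seen: set[int] = set()
    for name, atoms in fragments.items():
        overlap = seen.intersection(atoms)
        if overlap:
            raise ValueError(f"fragment {name!r} overlaps a previous group on atoms {sorted(overlap)}")
        if len(set(atoms)) != len(tuple(atoms)):
            raise ValueError(f"fragment {name!r} lists an atom twice")
        seen.update(atoms)
    source = profile.atom_kappa if profile.atom_kappa is not None else profile.atom_force
    if source is None:
        raise ValueError("no per-atom curves to aggregate")
    profile.fragments = {
        name: source[:, list(atoms)].sum(axis=1) for name, atoms in fragments.items()
    }
    return profile


def write_decomposition_table(
    profile: DecompositionProfile, path, atoms: tuple[int, ...] | None = None
) -> Path:
    """TSV of per-atom kappa_A curves (plus atoms/bonds sums when present).

    Endpoint rows are omitted when the atoms/bonds split is present,
    since their one-sided second derivatives are unreliable.
    """
    path = Path(path)
    if profile.atom_kappa is None:
        raise ValueError("compute kappa decomposition before writing")
    N = profile.atom_kappa.shape[1]
    atoms = tuple(range(N)) if atoms is None else atoms
    header = ["xi"] + [f"kappa_A{a}" for a in atoms]
    has_split = profile.kappa_atoms is not None
    if has_split:
        header += ["kappa_atoms", "kappa_bonds"]
    if profile.fragments:
        header += [f"frag_{name}" for name in profile.fragments]
    lines = [f"# units: {profile.units_note}", "\t".join(header)]
    rows = range(len(profile.xi))
    if has_split:
        rows = range(1, len(profile.xi) - 1)
    for i in rows:
        vals = [f"{profile.xi[i]:.6f}"] + [f"{profile.atom_kappa[i, a]:.8f}" for a in atoms]
        if has_split:
            vals += [f"{profile.kappa_atoms[i]:.8f}", f"{profile.kappa_bonds[i]:.8f}"]
        if profile.fragments:
            vals += [f"{curve[i]:.8f}" for curve in profile.fragments.values()]
        lines.append("\t".join(vals))
    path.write_text("\n".join(lines) + "\n")
    return path
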