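"""Reaction force analysis along an intrinsic reaction coordinate.

Given a discretized IRC path — energies E(xi) sampled on a mass-weighted
reaction coordinate xi (amu^(1/2)*bohr), with the transition state at
xi = 0 — this module computes

    F(xi)     = -dE/dxi          (reaction force)
    kappa(xi) = d^2E/dxi^2 = -dF/dxi   (reaction force constant)

by finite differences: at each interior point the derivative is the
average of the forward and backward one-sided slopes; the first and last
points use the one-sided slope alone.  On a uniform grid the averaged
scheme coincides with the central difference and is exact for
quadratics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .geometry import Geometry
from .units import HARTREE_TO_KCAL_PER_MOL

__all__ = [
    "IRCPath",
    "RFAProfile",
    "finite_difference",
    "reaction_force",
    "reaction_force_constant",
    "rfa_profile",
    "write_rfa_table",
    "plot_rfa",
]


@dataclasses.dataclass
class IRCPath:
    """A discretized IRC path.

    Attributes
    ----------
    xi : ndarray, shape (P,)
        Strictly increasing reaction-coordinate grid in amu^(1/2)*bohr;
        negative values are the reactant side, positive the product
        side, the TS sits at xi = 0.
    energy : ndarray, shape (P,)
        Electronic energy in Hartree at each point.
    geometries : list of Geometry
        Cartesian geometry (Angstrom) at each point.
    forces : ndarray, shape (P, N, 3) or None
        Per-atom force vectors (negative energy gradients) in
        Hartree/bohr; None when the backend did not print forces.
    name : str
        Label used in reports.
    """

    xi: np.ndarray
    energy: np.ndarray
    geometries: list[Geometry]
    forces: np.ndarray | None = None
    name: str = "path"

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.xi.ndim != 1:
            raise ValueError("xi must be one-dimensional")
        if len(self.xi) != len(self.energy) or len(self.xi) != len(self.geometries):
            raise ValueError("xi, energy and geometries must share length")
        if len(self.xi) < 3:
            raise ValueError("an IRC path needs at least 3 points for differentiation")
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("xi grid must be strictly increasing")
        n_atoms = {g.n_atoms for g in self.geometries}
        if len(n_atoms) != 1:
            raise ValueError("all path geometries must have the same atom count")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (len(self.xi), self.n_atoms, 3):
                raise ValueError("forces must have shape (n_points, n_atoms, 3)")

    @property
    def has_forces(self) -> bool:
        return self.forces is not None

    @property
    def n_points(self) -> int:
        return len(self.xi)

    @property
    def n_atoms(self) -> int:
        return self.geometries[0].n_atoms

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (P, N, 3), Angstrom."""
        return np.stack([g.coords for g in self.geometries])


@dataclasses.dataclass
class RFAProfile:
    """F(xi) and kappa(xi) profiles derived from an IRC path.

    Units: force in Hartree/(amu^(1/2)*bohr), kappa in
    Hartree/(amu^(1/2)*bohr)^2; reports may convert the energy scale to
    kcal/mol via the standard Hartree factor.
    """

    xi: np.ndarray
    energy: np.ndarray
    force: np.ndarray | None = None
    kappa: np.ndarray | None = None
    units_note: str = "xi: amu^(1/2)*bohr; E: Hartree; F: Hartree/xi; kappa: Hartree/xi^2"


def finite_difference(values, xi) -> np.ndarray:
    """Differentiate sampled values on a strictly increasing grid.

    Interior points get the mean of the forward and backward one-sided
    slopes; the endpoints get the single available one-sided slope.
    Exact for linear data everywhere and for quadratics at interior
    points of a uniform grid.
    """
    values = np.asarray(values, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if values.shape[0] != xi.shape[0]:
        raise ValueError("values and grid must share length")
    if len(xi) < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(xi) <= 0):
        raise ValueError("grid must be strictly increasing")
    if np.any(~np.isfinite(values)):
        raise ValueError("non-finite values on the grid; refusing to differentiate")
    fwd = np.diff(values, axis=0) / np.diff(xi).reshape(-1, *([1] * (values.ndim - 1)))
    out = np.empty_like(values)
    out[0] = fwd[0]
    out[-1] = fwd[-1]
    out[1:-1] = 0.5 * (fwd[1:] + fwd[:-1])
    return out


def reaction_force(path: IRCPath) -> RFAProfile:
    """Compute the reaction force F(xi) = -dE/dxi of a path."""
    force = -finite_difference(path.energy, path.xi)
    return RFAProfile(xi=path.xi.copy(), energy=path.energy.copy(), force=force)


def reaction_force_constant(profile: RFAProfile) -> RFAProfile:
    """Fill in kappa(xi) = -dF/dxi on a profile whose force is computed."""
    if profile.force is None:
        raise ValueError("compute the reaction force first")
    profile.kappa = -finite_difference(profile.force, profile.xi)
    return profile


def rfa_profile(path: IRCPath) -> RFAProfile:
    """Convenience: full E/F/kappa profile from a path."""
    return reaction_force_constant(reaction_force(path))


def write_rfa_table(profile: RFAProfile, path, kcal: bool = False) -> Path:
    """Write the profile as a TSV with a units header line.

    With ``kcal=True`` the energy scale converts to kcal/mol (xi stays
    mass-weighted), matching the common plotting convention.
    """
    path = Path(path)
    scale = HARTREE_TO_KCAL_PER_MOL if kcal else 1.0
    eunit = "kcal/mol" if kcal else "Hartree"
    lines = [
        f"# units: xi amu^(1/2)*bohr | E {eunit} | F {eunit}/xi | kappa {eunit}/xi^2",
        "xi\tE\tF\tkappa",
    ]
    for i in range(len(profile.xi)):
        f = profile.force[i] * scale if profile.force is not None else float("nan")
        k = profile.kappa[i] * scale if profile.kappa is not None else float("nan")
        lines.append(
            f"{profile.xi[i]:.6f}\t{profile.energy[i] * scale:.8f}\t{f:.8f}\t{k:.8f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def plot_rfa(profile: RFAProfile, path, kcal: bool = True) -> Path:
    """Three-panel plot of E, F and kappa against xi."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scale = HARTREE_TO_KCAL_PER_MOL if kcal else 1.0
    eunit = "kcal/mol" if kcal else "Hartree"
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    rel_e = (profile.energy - profile.energy.min()) * scale
    axes[0].plot(profile.xi, rel_e)
    axes[0].set_ylabel(f"E ({eunit})")
    if profile.force is not None:
        axes[1].plot(profile.xi, profile.force * scale)
        axes[1].set_ylabel(f"F ({eunit}/$\\xi$)")
    if profile.kappa is not None:
        axes[2].plot(profile.xi, profile.kappa * scale)
        axes[2].set_ylabel(f"$\\kappa$ ({eunit}/$\\xi^2$)")
    for ax in axes:
        ax.axvline(0.0, color="grey", lw=0.5)
        ax.set_xlabel(r"$\xi$ (amu$^{1/2}$ bohr)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
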