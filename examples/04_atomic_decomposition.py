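"""Hellmann-Feynman decomposition of F and kappa into atomic terms.

On a synthetic path with exactly self-consistent forces, the summed
atomic contributions reproduce the total profiles up to the
finite-difference truncation error; with Hessians along the path, kappa
further splits into an atoms (diagonal) and a bonds (pairwise) part.
"""

import numpy as np

from daforge import (
    PathSpec,
    atomic_force_decomposition,
    atomic_kappa_decomposition,
    atoms_bonds_split,
    diatomic_harmonic_path,
    make_hessians,
    make_path,
    rfa_profile,
)

spec = PathSpec(n_points_per_direction=50, step=0.04, n_atoms=4, seed=3)
path = make_path(spec)
profile = rfa_profile(path)
dec = atomic_kappa_decomposition(atomic_force_decomposition(path), path)

f_resid = np.abs(dec.atom_force.sum(axis=1) - profile.force)[1:-1].max()
k_resid = np.abs(dec.atom_kappa.sum(axis=1) - profile.kappa)[2:-2].max()
print(f"sum_A F_A vs F:     max residual {f_resid:.2e} "
      f"({f_resid / np.abs(profile.force).max():.1e} relative)")
print(f"sum_A kappa_A vs kappa: max residual {k_resid:.2e} "
      f"({k_resid / np.abs(profile.kappa).max():.1e} relative)")

dec = atoms_bonds_split(path, make_hessians(spec), dec)
s_resid = np.abs(dec.kappa_atoms + dec.kappa_bonds - profile.kappa)[2:-2].max()
print(f"kappa_atoms + kappa_bonds vs kappa: max residual {s_resid:.2e}")

# analytic diatomic: the split has a closed form
dpath, dhess = diatomic_harmonic_path(k=0.5)
ddec = atoms_bonds_split(dpath, dhess)
mid = dpath.n_points // 2
print(f"harmonic diatomic (k = 0.5): kappa_atoms = {ddec.kappa_atoms[mid]:.3f}, "
      f"kappa_bonds = {ddec.kappa_bonds[mid]:.3f}  (k/2 each, summing to k)")
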