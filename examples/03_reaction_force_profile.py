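"""Reaction force analysis of a synthetic double-well IRC path.

F(xi) = -dE/dxi vanishes at the TS and at both minima; the reaction
force constant kappa(xi) = -dF/dxi is negative around the barrier top,
the signature of the bond-reorganization region.
"""

import numpy as np

from daforge import PathSpec, make_path, rfa_profile

spec = PathSpec(
    functional_form="double_well_barrier",
    n_points_per_direction=40, step=0.1, n_atoms=4, seed=0,
)
path = make_path(spec)
profile = rfa_profile(path)

ts = int(np.argmin(np.abs(path.xi)))
print(f"path: {path.n_points} points, xi in [{path.xi[0]:.1f}, {path.xi[-1]:.1f}]")
print(f"F at the TS grid point:      {profile.force[ts]: .6f} Hartree/xi")
print(f"kappa at the TS grid point:  {profile.kappa[ts]: .6f} Hartree/xi^2 (negative: barrier top)")
# the characteristic F extrema lie between the two energy minima
e = path.energy
wells = sorted(
    i for i in range(1, len(e) - 1) if e[i] < e[i - 1] and e[i] < e[i + 1]
)
lo, hi = wells[0], wells[-1]
seg = slice(lo, hi + 1)
i_min = lo + int(np.argmin(profile.force[seg]))
i_max = lo + int(np.argmax(profile.force[seg]))
print(f"between the wells: F minimum {profile.force[i_min]: .4f} at xi = {path.xi[i_min]: .2f}, "
      f"maximum {profile.force[i_max]: .4f} at xi = {path.xi[i_max]: .2f}")
print("(the two extrema bracket the TS and mark the bond-reorganization region)")
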