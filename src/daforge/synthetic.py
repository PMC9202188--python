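"""Analytic, self-consistent synthetic IRC paths and Hessians.

Every numeric stage of the workflow (parsers, reaction-force analysis,
atomic decomposition) is testable without any electronic-structure
software: this module builds discretized paths whose energies,
geometries, per-atom forces and Hessians all derive from closed-form
functions and are mutually consistent *exactly*, so conservation
identities have an exact target and any residual is attributable to the
finite-difference truncation alone.

Construction:

* E(xi) comes from a chosen functional form (inverted parabola, quartic
  double well with optional cubic asymmetry, or a raw polynomial).
* Each atom follows a trajectory R_A(xi) = base + linear*xi +
  amp*sin(freq*xi + phase), differentiable in closed form.
* Per-atom forces are free smooth functions except for one reserved
  component (the x component of the last atom, whose tangent is pinned
  to a nonzero constant); that component is solved point-by-point so
  that sum_A F_A . dR_A/dxi = -dE/dxi holds exactly.
* Hessians start from a seeded random symmetric matrix and receive a
  rank-one correction along the path tangent so that the second
  derivative of E along the path is reproduced exactly.

The fixtures are mathematical, not chemical: they mimic the shape of a
reaction profile, not Diels-Alder energetics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .geometry import Geometry
from .rfa import IRCPath
from .rfd import HessianSeries
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "PathSpec",
    "make_path",
    "make_hessians",
    "write_fake_outputs",
    "energy_function",
    "diatomic_harmonic_path",
]

_ELEMENT_CYCLE = ("C", "H", "O", "N")


@dataclasses.dataclass(frozen=True)
class PathSpec:
    """Recipe for one synthetic path; generation is a pure function of it."""

    functional_form: str = "double_well_barrier"
    parameters: tuple[tuple[str, float], ...] = ()
    n_points_per_direction: int = 5
    step: float = 0.8
    n_atoms: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points_per_direction < 3:
            raise ValueError("need at least 3 points per direction")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_atoms < 1:
            raise ValueError("need at least one atom")
        if self.functional_form not in ("inverted_parabola", "double_well_barrier", "polynomial"):
            raise ValueError(f"unknown functional form {self.functional_form!r}")

    @property
    def params(self) -> dict[str, float]:
        return dict(self.parameters)


def energy_function(spec: PathSpec):
    """Return closed-form (E, dE/dxi, d2E/dxi2) callables for a spec."""
    p = spec.params
    if spec.functional_form == "inverted_parabola":
        a = p.get("a", 0.05)
        e0 = p.get("e0", 0.0)
        return (
            lambda x: e0 - a * x**2,
            lambda x: -2.0 * a * x,
            lambda x: -2.0 * a * np.ones_like(x),
        )
    if spec.functional_form == "double_well_barrier":
        # quartic double well; asymmetry c skews the two wells to emulate
        # asynchronous profiles
        a = p.get("a", 0.01)
        b = p.get("b", 0.125)
        c = p.get("c", 0.0)
        e0 = p.get("e0", 0.0)
        return (
            lambda x: a * x**4 - b * x**2 + c * x**3 + e0,
            lambda x: 4 * a * x**3 - 2 * b * x + 3 * c * x**2,
            lambda x: 12 * a * x**2 - 2 * b + 6 * c * x,
        )
    # polynomial: parameters c0, c1, c2, ... are ascending coefficients
    coeffs = [v for k, v in sorted(p.items()) if k.startswith("c")]
    poly = np.polynomial.Polynomial(coeffs if coeffs else [0.0])
    d1 = poly.deriv(1)
    d2 = poly.deriv(2)
    return poly, d1, d2


def _motion_arrays(spec: PathSpec):
    """Seeded per-atom trajectory parameters (all shape (N, 3), Angstrom)."""
    rng = np.random.default_rng(spec.seed)
    N = spec.n_atoms
    base = rng.uniform(-2.0, 2.0, size=(N, 3))
    linear = rng.uniform(-0.3, 0.3, size=(N, 3))
    amp = rng.uniform(0.0, 0.15, size=(N, 3))
    freq = rng.uniform(0.4, 1.2, size=(N, 3))
    phase = rng.uniform(0.0, 2 * np.pi, size=(N, 3))
    # reserve the last atom's x channel: constant nonzero tangent so the
    # force-consistency solve below is always well-posed
    linear[N - 1, 0] = 1.0
    amp[N - 1, 0] = 0.0
    return base, linear, amp, freq, phase


def _build(spec: PathSpec):
    """All closed-form arrays for a spec: grid, energetics, motion, forces."""
    n = spec.n_points_per_direction
    xi = spec.step * np.arange(-n, n + 1, dtype=float)
    E, dE, d2E = energy_function(spec)
    energy = E(xi)
    e_prime = dE(xi)
    e_second = d2E(xi)

    base, linear, amp, freq, phase = _motion_arrays(spec)
    # R_A(xi) and closed-form derivatives, shape (P, N, 3), Angstrom
    arg = freq[None] * xi[:, None, None] + phase[None]
    coords = base[None] + linear[None] * xi[:, None, None] + amp[None] * np.sin(arg)
    vel = linear[None] + (amp * freq)[None] * np.cos(arg)  # dR/dxi, Angstrom per xi
    acc = -(amp * freq**2)[None] * np.sin(arg)  # d2R/dxi2

    # free smooth force components, then solve the reserved channel so the
    # projection identity sum_A F_A . t_A = -dE/dxi holds exactly (t in bohr)
    rng = np.random.default_rng(spec.seed + 1)
    N = spec.n_atoms
    fp = rng.uniform(-0.02, 0.02, size=(N, 3))
    fq = rng.uniform(-0.02, 0.02, size=(N, 3))
    fr = rng.uniform(0.4, 1.2, size=(N, 3))
    fs = rng.uniform(0.0, 2 * np.pi, size=(N, 3))
    forces = fp[None] + fq[None] * np.sin(fr[None] * xi[:, None, None] + fs[None])
    t_bohr = vel * ANGSTROM_TO_BOHR
    forces[:, N - 1, 0] = 0.0
    partial = np.einsum("pax,pax->p", forces, t_bohr)
    forces[:, N - 1, 0] = (-e_prime - partial) / t_bohr[:, N - 1, 0]

    elements = [_ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)] for i in range(N)]
    return {
        "xi": xi,
        "energy": energy,
        "e_prime": e_prime,
        "e_second": e_second,
        "coords": coords,
        "vel": vel,
        "acc": acc,
        "forces": forces,
        "elements": elements,
    }


def make_path(spec: PathSpec, name: str = "synthetic") -> IRCPath:
    """Build a discretized IRC path from a spec (pure in (spec, seed))."""
    b = _build(spec)
    geometries = [
        Geometry(b["elements"], b["coords"][i], provenance="irc_point")
        for i in range(len(b["xi"]))
    ]
    return IRCPath(
        xi=b["xi"], energy=b["energy"], geometries=geometries, forces=b["forces"], name=name
    )


def make_hessians(spec: PathSpec, scale: float = 0.05) -> HessianSeries:
    """Seeded symmetric Hessians consistent with d2E/dxi2 along the path.

    A rank-one correction along the (analytic) full-path tangent T makes
    T^T H T equal the closed-form second derivative of E along the path
    minus the curvature term sum_A F_A . d2R_A/dxi2, exactly.
    """
    b = _build(spec)
    P = len(b["xi"])
    N = spec.n_atoms
    rng = np.random.default_rng(spec.seed + 2)
    raw = rng.uniform(-scale, scale, size=(P, 3 * N, 3 * N))
    H = 0.5 * (raw + np.swapaxes(raw, 1, 2))
    T = (b["vel"] * ANGSTROM_TO_BOHR).reshape(P, 3 * N)
    target = b["e_second"] + np.einsum("pax,pax->p", b["forces"], b["acc"] * ANGSTROM_TO_BOHR)
    current = np.einsum("pi,pij,pj->p", T, H, T)
    tnorm2 = np.einsum("pi,pi->p", T, T)
    corr = (target - current) / tnorm2**2
    H = H + corr[:, None, None] * np.einsum("pi,pj->pij", T, T)
    return HessianSeries(H)


def diatomic_harmonic_path(
    k: float = 0.5, d0_bohr: float = 2.5, n_points_per_direction: int = 8, step: float = 0.1
):
    """Two atoms on a harmonic spring, symmetric stretch along x.

    The interatomic distance is d0 + xi (bohr), E = k/2 * xi^2 Hartree,
    and both atoms carry the textbook restoring forces; the analytic
    Hessian has the +/-k block structure.  Returns (IRCPath,
    HessianSeries).
    """
    n = n_points_per_direction
    xi = step * np.arange(-n, n + 1, dtype=float)
    P = len(xi)
    energy = 0.5 * k * xi**2
    coords_bohr = np.zeros((P, 2, 3))
    coords_bohr[:, 0, 0] = -(d0_bohr + xi) / 2.0
    coords_bohr[:, 1, 0] = +(d0_bohr + xi) / 2.0
    forces = np.zeros((P, 2, 3))
    forces[:, 0, 0] = +k * xi  # pulls atom 0 back toward +x when stretched
    forces[:, 1, 0] = -k * xi
    geometries = [
        Geometry(["C", "C"], coords_bohr[i] * BOHR_TO_ANGSTROM, provenance="irc_point")
        for i in range(P)
    ]
    path = IRCPath(xi=xi, energy=energy, geometries=geometries, forces=forces, name="diatomic")
    H = np.zeros((P, 6, 6))
    H[:, 0, 0] = H[:, 3, 3] = k
    H[:, 0, 3] = H[:, 3, 0] = -k
    return path, HessianSeries(H)


def write_fake_outputs(
    path: IRCPath,
    dialect: str,
    out_dir,
    truncated: bool = False,
    frequencies: list[float] | None = None,
) -> list[Path]:
    """Serialize a path (plus an optional frequency set) as backend outputs.

    ``dialect`` is "plain" (the package's own path format) or "gaussian"
    (the simplified Gaussian-style log dialect).  With ``truncated=True``
    an additionally cut-off copy is written to exercise parser error
    paths.
    """
    from . import qm_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if dialect == "plain":
        target = out_dir / f"{path.name}.ircpath"
        qm_io.write_path_file(path, target)
    elif dialect == "gaussian":
        target = out_dir / f"{path.name}_irc.log"
        qm_io.write_gaussian_irc_log(path, target)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    written.append(target)
    if truncated:
        text = target.read_text().splitlines()
        cut = out_dir / f"{target.stem}_truncated{target.suffix}"
        cut.write_text("\n".join(text[: max(3, len(text) // 2)]) + "\n")
        written.append(cut)
    if frequencies is not None:
        freq_file = out_dir / f"{path.name}_freq.log"
        qm_io.write_gaussian_freq_log(frequencies, freq_file)
        written.append(freq_file)
    return written
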