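"""Hellmann-Feynman atomic decomposition of F and kappa."""

import numpy as np
import pytest

from daforge import rfd, synthetic
from daforge.geometry import Geometry
from daforge.rfa import IRCPath, rfa_profile
from daforge.rfd import (
    CapabilityError,
    HessianSeries,
    atomic_force_decomposition,
    atomic_kappa_decomposition,
    atoms_bonds_split,
    fragment_aggregate,
    path_tangents,
)
from daforge.units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM


def path_from_coords(xi, coords_bohr, energy=None, forces=None, elements=None):
    coords_A = np.asarray(coords_bohr) * BOHR_TO_ANGSTROM
    P, N = coords_A.shape[:2]
    elements = elements or ["C"] * N
    geoms = [Geometry(list(elements), coords_A[i]) for i in range(P)]
    energy = np.zeros(P) if energy is None else energy
    return IRCPath(xi=np.asarray(xi, float), energy=energy, geometries=geoms, forces=forces)


def one_atom_harmonic(k=0.3, h=0.05, n=40):
    """Single atom moving as x = xi (bohr) on E = k/2 xi^2; F = (-k xi, 0, 0)."""
    xi = h * np.arange(-n, n + 1, dtype=float)
    coords = np.zeros((len(xi), 1, 3))
    coords[:, 0, 0] = xi
    forces = np.zeros((len(xi), 1, 3))
    forces[:, 0, 0] = -k * xi
    return path_from_coords(xi, coords, energy=0.5 * k * xi**2, forces=forces), k


class TestPathTangents:
    def test_linear_motion_gives_unit_tangent(self):
        xi = np.linspace(-1, 1, 9)
        coords = np.zeros((9, 1, 3))
        coords[:, 0, 0] = xi  # bohr
        t = path_tangents(path_from_coords(xi, coords))
        np.testing.assert_allclose(t, [[[1.0, 0.0, 0.0]]] * 9, atol=1e-12)

    def test_rigid_translation_shares_tangent_across_atoms(self):
        xi = np.linspace(-1, 1, 9)
        base = np.random.default_rng(0).normal(size=(3, 3))
        v = np.array([0.4, -0.2, 0.1])
        coords = base[None] + xi[:, None, None] * v[None, None]
        t = path_tangents(path_from_coords(xi, coords))
        for a in range(3):
            np.testing.assert_allclose(t[:, a], t[:, 0], atol=1e-12)

    def test_circular_motion_unit_speed(self):
        xi = np.arange(-2, 2.0001, 0.01)
        coords = np.zeros((len(xi), 1, 3))
        coords[:, 0, 0] = np.cos(xi)
        coords[:, 0, 1] = np.sin(xi)
        t = path_tangents(path_from_coords(xi, coords))
        speed = np.linalg.norm(t, axis=2)[1:-1, 0]
        np.testing.assert_allclose(speed, 1.0, atol=1e-4)

    def test_mismatched_atom_counts_rejected(self):
        xi = np.linspace(-1, 1, 3)
        geoms = [
            Geometry(["C"], np.zeros((1, 3))),
            Geometry(["C", "C"], np.zeros((2, 3))),
            Geometry(["C"], np.zeros((1, 3))),
        ]
        with pytest.raises(ValueError):
            IRCPath(xi=xi, energy=np.zeros(3), geometries=geoms)


class TestAtomicForceDecomposition:
    def test_one_atom_harmonic_closed_form(self):
        path, k = one_atom_harmonic()
        dec = atomic_force_decomposition(path)
        # single contribution equals the total F = -dE/dxi = -k xi
        np.testing.assert_allclose(
            dec.atom_force[1:-1, 0], -k * path.xi[1:-1], atol=1e-10
        )
        prof = rfa_profile(path)
        np.testing.assert_allclose(dec.atom_force[1:-1, 0], prof.force[1:-1], atol=1e-10)

    def test_static_atom_contributes_zero(self):
        xi = np.linspace(-1, 1, 11)
        coords = np.zeros((11, 2, 3))
        coords[:, 0, 0] = xi  # atom 0 moves, atom 1 static
        forces = np.random.default_rng(1).normal(size=(11, 2, 3))
        path = path_from_coords(xi, coords, forces=forces)
        dec = atomic_force_decomposition(path)
        np.testing.assert_allclose(dec.atom_force[:, 1], 0.0, atol=1e-12)

    def test_conservation_against_energy_route(self, fine_path):
        dec = atomic_force_decomposition(fine_path)
        prof = rfa_profile(fine_path)
        resid = np.abs(dec.atom_force.sum(axis=1) - prof.force)[1:-1]
        assert resid.max() / np.abs(prof.force).max() < 1e-3

    def test_forceless_path_rejected(self, fine_path):
        bare = IRCPath(
            xi=fine_path.xi, energy=fine_path.energy,
            geometries=fine_path.geometries, forces=None,
        )
        with pytest.raises(CapabilityError):
            atomic_force_decomposition(bare)


class TestAtomicKappaDecomposition:
    def test_one_atom_harmonic_equals_total(self):
        path, k = one_atom_harmonic()
        dec = atomic_kappa_decomposition(atomic_force_decomposition(path), path)
        prof = rfa_profile(path)
        # kappa = d2E/dxi2 = +k, carried entirely by the single atom
        np.testing.assert_allclose(dec.atom_kappa[2:-2, 0], k, atol=1e-10)
        np.testing.assert_allclose(dec.atom_kappa[2:-2, 0], prof.kappa[2:-2], atol=1e-10)

    def test_zero_tangent_atom_zero_kappa(self):
        xi = np.linspace(-1, 1, 11)
        coords = np.zeros((11, 2, 3))
        coords[:, 0, 0] = xi
        forces = np.random.default_rng(1).normal(size=(11, 2, 3))
        path = path_from_coords(xi, coords, forces=forces)
        dec = atomic_kappa_decomposition(atomic_force_decomposition(path), path)
        np.testing.assert_allclose(dec.atom_kappa[:, 1], 0.0, atol=1e-12)

    def test_conservation_against_energy_route(self, fine_path):
        dec = atomic_kappa_decomposition(atomic_force_decomposition(fine_path), fine_path)
        prof = rfa_profile(fine_path)
        resid = np.abs(dec.atom_kappa.sum(axis=1) - prof.kappa)[2:-2]
        assert resid.max() / np.abs(prof.kappa).max() < 1e-3


class TestAtomsBondsSplit:
    def test_diatomic_harmonic_closed_form(self):
        """Symmetric stretch of a harmonic diatomic: each atom's diagonal
        term is k/4, the pair term carries k/4 twice, and the sum equals
        the energy-route kappa = k."""
        path, H = synthetic.diatomic_harmonic_path(k=0.5)
        dec = atoms_bonds_split(path, H)
        prof = rfa_profile(path)
        np.testing.assert_allclose(dec.kappa_AA[2:-2], 0.125, atol=1e-10)  # k/4 each
        np.testing.assert_allclose(dec.kappa_atoms[2:-2], 0.25, atol=1e-10)  # k/2
        np.testing.assert_allclose(dec.kappa_bonds[2:-2], 0.25, atol=1e-10)  # k/2
        total = dec.kappa_atoms + dec.kappa_bonds
        np.testing.assert_allclose(total[2:-2], prof.kappa[2:-2], atol=1e-10)

    def test_block_diagonal_hessian_has_zero_bond_component(self, fine_path):
        P, N = fine_path.n_points, fine_path.n_atoms
        rng = np.random.default_rng(2)
        H = np.zeros((P, 3 * N, 3 * N))
        for a in range(N):
            blk = rng.normal(size=(P, 3, 3))
            blk = 0.5 * (blk + np.swapaxes(blk, 1, 2))
            H[:, 3 * a : 3 * a + 3, 3 * a : 3 * a + 3] = blk
        dec = atoms_bonds_split(fine_path, HessianSeries(H))
        np.testing.assert_allclose(dec.kappa_bonds, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            dec.kappa_atoms, dec.kappa_AA.sum(axis=1), atol=1e-12
        )

    def test_randomized_hessian_symmetry_and_conservation(self, fine_spec, fine_path):
        hess = synthetic.make_hessians(fine_spec)
        dec = atoms_bonds_split(fine_path, hess)
        np.testing.assert_allclose(
            dec.kappa_AB, np.swapaxes(dec.kappa_AB, 1, 2), atol=1e-12
        )
        prof = rfa_profile(fine_path)
        resid = np.abs(dec.kappa_atoms + dec.kappa_bonds - prof.kappa)[2:-2]
        assert resid.max() / np.abs(prof.kappa).max() < 1e-3

    def test_translation_invariance_of_all_curves(self, fine_spec, fine_path):
        hess = synthetic.make_hessians(fine_spec)
        ref = atoms_bonds_split(fine_path, hess)
        ref = atomic_kappa_decomposition(ref, fine_path)
        shifted_geoms = [g.copy() for g in fine_path.geometries]
        for g in shifted_geoms:
            g.coords = g.coords + np.array([3.0, -7.0, 11.0])
        shifted = IRCPath(
            xi=fine_path.xi, energy=fine_path.energy,
            geometries=shifted_geoms, forces=fine_path.forces,
        )
        out = atoms_bonds_split(shifted, hess)
        out = atomic_kappa_decomposition(out, shifted)
        np.testing.assert_allclose(out.atom_force, ref.atom_force, atol=1e-9)
        np.testing.assert_allclose(out.atom_kappa, ref.atom_kappa, atol=1e-9)
        np.testing.assert_allclose(out.kappa_atoms, ref.kappa_atoms, atol=1e-9)
        np.testing.assert_allclose(out.kappa_bonds, ref.kappa_bonds, atol=1e-9)

    def test_missing_hessians_dimension_mismatch(self, fine_path):
        bad = HessianSeries(np.zeros((fine_path.n_points, 6, 6)))
        with pytest.raises(CapabilityError):
            atoms_bonds_split(fine_path, bad)


class TestFragmentAggregate:
    @pytest.fixture
    def decomposed(self, fine_path):
        return atomic_kappa_decomposition(atomic_force_decomposition(fine_path), fine_path)

    def test_all_atoms_fragment_equals_total(self, decomposed, fine_path):
        frag = fragment_aggregate(decomposed, {"all": tuple(range(fine_path.n_atoms))})
        np.testing.assert_allclose(
            frag.fragments["all"], decomposed.atom_kappa.sum(axis=1), atol=1e-12
        )

    def test_singleton_fragment_equals_atom_curve(self, decomposed):
        frag = fragment_aggregate(decomposed, {"a2": (2,)})
        np.testing.assert_allclose(frag.fragments["a2"], decomposed.atom_kappa[:, 2], atol=0)

    def test_complementary_fragments_sum_to_total(self, decomposed, fine_path):
        N = fine_path.n_atoms
        frag = fragment_aggregate(
            decomposed, {"left": tuple(range(N // 2)), "right": tuple(range(N // 2, N))}
        )
        total = frag.fragments["left"] + frag.fragments["right"]
        np.testing.assert_allclose(total, decomposed.atom_kappa.sum(axis=1), atol=1e-12)

    def test_overlapping_fragments_rejected(self, decomposed):
        with pytest.raises(ValueError):
            fragment_aggregate(decomposed, {"a": (0, 1), "b": (1, 2)})
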