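"""Retro-Diels-Alder transformation on molecular graphs.

A Diels-Alder cycloadduct contains a cyclohexene ring whose endocyclic
C=C marks the former diene core and whose two opposite sp3 carbons come
from the dienophile.  This module locates those reactive sites,
enumerates competing sites when several cyclohexene substructures are
present, and performs the formal retro transformation: delete the two
sigma bonds formed in the cycloaddition and restore the diene and
dienophile pi systems.

Atom indices are 0-based throughout; files that use 1-based numbering
convert at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit parse warnings for deliberately invalid lines are reported through
# our own logger instead.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Cycloadduct",
    "ReactiveSite",
    "RetroProducts",
    "SmilesFileError",
    "parse_smiles_file",
    "find_reactive_sites",
    "retro_transform",
    "forward_check",
]


class SmilesFileError(RuntimeError):
    """Fatal problem with the cycloadduct SMILES input file."""


@dataclasses.dataclass
class Cycloadduct:
    """A parsed cycloadduct: canonical SMILES, molecular graph, source line."""

    smiles: str
    mol: Chem.Mol
    source_line: int

    @classmethod
    def from_smiles(cls, smiles: str, source_line: int = 0) -> "Cycloadduct":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        return cls(Chem.MolToSmiles(mol), mol, source_line)

    @property
    def formula(self) -> str:
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        return CalcMolFormula(self.mol)


@dataclasses.dataclass(frozen=True)
class ReactiveSite:
    """Ordered six-atom reactive site of a cycloadduct.

    ``diene_atoms`` = (d1, d2, d3, d4) with d2=d3 the endocyclic double
    bond; ``dienophile_atoms`` = (e1, e2), the two ring carbons neither
    in nor adjacent to that double bond.  Around the ring the cyclic
    order is d1-d2-d3-d4-e2-e1.  The bonds d1-e1 and d4-e2 are the sigma
    bonds formed in the forward cycloaddition and broken in retro.
    """

    diene_atoms: tuple[int, int, int, int]
    dienophile_atoms: tuple[int, int]

    @property
    def ring_atoms(self) -> tuple[int, ...]:
        d1, d2, d3, d4 = self.diene_atoms
        e1, e2 = self.dienophile_atoms
        return (d1, d2, d3, d4, e2, e1)

    @property
    def atom_set(self) -> frozenset[int]:
        return frozenset(self.ring_atoms)

    @property
    def forming_bonds(self) -> tuple[tuple[int, int], tuple[int, int]]:
        d1, _, _, d4 = self.diene_atoms
        e1, e2 = self.dienophile_atoms
        return ((d1, e1), (d4, e2))


@dataclasses.dataclass
class RetroProducts:
    """Products of a retro-Diels-Alder transformation."""

    diene_smiles: str
    dienophile_smiles: str  # empty when the reaction is intramolecular
    combined_smiles: str
    intramolecular: bool
    atom_map: dict[int, int]  # product atom index -> adduct atom index
    product_mol: Chem.Mol
    site: ReactiveSite


def parse_smiles_file(path) -> list[Cycloadduct]:
    """Read a plain-text file of cycloadduct SMILES, one per line.

    Blank lines and ``#`` comments are ignored.  Invalid SMILES are
    logged and skipped; a file with no valid line at all is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise SmilesFileError(f"SMILES file not found: {path}")
    adducts: list[Cycloadduct] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            adducts.append(Cycloadduct.from_smiles(line, source_line=lineno))
        except ValueError:
            logger.warning("line %d: skipping invalid SMILES %r", lineno, line)
    if not adducts:
        raise SmilesFileError(f"no valid SMILES found in {path}")
    return adducts


def _cyclohexene_rings(mol: Chem.Mol):
    """Yield (ring_atom_tuple, double_bond_pair) for each six-membered
    all-carbon non-aromatic ring with exactly one endocyclic C=C."""
    ring_info = mol.GetRingInfo()
    seen: set[frozenset[int]] = set()
    for ring in ring_info.AtomRings():
        if len(ring) != 6:
            continue
        key = frozenset(ring)
        if key in seen:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if any(a.GetSymbol() != "C" for a in atoms):
            continue
        if any(a.GetIsAromatic() for a in atoms):
            continue
        doubles = []
        ok = True
        for k in range(6):
            i, j = ring[k], ring[(k + 1) % 6]
            bond = mol.GetBondBetweenAtoms(i, j)
            if bond.GetIsAromatic():
                ok = False
                break
            if bond.GetBondType() == Chem.BondType.DOUBLE:
                doubles.append((i, j))
            elif bond.GetBondType() != Chem.BondType.SINGLE:
                ok = False
                break
        if ok and len(doubles) == 1:
            seen.add(key)
            yield ring, doubles[0]


def _site_from_ring(ring: tuple[int, ...], double_pair: tuple[int, int]) -> ReactiveSite:
    """Build the canonical ReactiveSite for a cyclohexene ring.

    The partition is fixed by the double-bond position: the alkene
    carbons and their ring neighbours form the diene-derived quartet;
    the remaining two ring atoms are the dienophile pair.  Orientation
    is canonicalized by taking d2 as the smaller-index alkene carbon.
    """
    n = 6
    # walk the ring so it is a cyclic sequence
    cyc = list(ring)
    i2, i3 = double_pair
    if i2 > i3:
        i2, i3 = i3, i2  # canonical orientation: d2 = min alkene index
    p2 = cyc.index(i2)
    # ensure traversal direction puts d3 right after d2
    if cyc[(p2 + 1) % n] != i3:
        cyc = cyc[::-1]
        p2 = cyc.index(i2)
        assert cyc[(p2 + 1) % n] == i3
    d2 = cyc[p2]
    d3 = cyc[(p2 + 1) % n]
    d4 = cyc[(p2 + 2) % n]
    e2 = cyc[(p2 + 3) % n]
    e1 = cyc[(p2 + 4) % n]
    d1 = cyc[(p2 + 5) % n]
    return ReactiveSite((d1, d2, d3, d4), (e1, e2))


def find_reactive_sites(adduct: Cycloadduct) -> list[ReactiveSite]:
    """Locate every Diels-Alder reactive site of a cycloadduct.

    One site is returned per distinct six-membered all-carbon ring
    carrying exactly one endocyclic (non-aromatic) C=C.  Multiple sites
    are competing retro pathways and are treated separately downstream.
    An empty list means the molecule is not recognised as a DA adduct.
    """
    sites = [_site_from_ring(ring, dbl) for ring, dbl in _cyclohexene_rings(adduct.mol)]
    # dedupe on the atom 6-set, order by smallest member index
    unique: dict[frozenset[int], ReactiveSite] = {}
    for s in sites:
        unique.setdefault(s.atom_set, s)
    return sorted(unique.values(), key=lambda s: min(s.atom_set))


class SiteRejection(RuntimeError):
    """The retro transformation at this site produces an invalid valence."""


def retro_transform(adduct: Cycloadduct, site: ReactiveSite) -> RetroProducts:
    """Perform the retro-Diels-Alder transformation at a reactive site.

    Bond bookkeeping: delete d1-e1 and d4-e2; promote d1-d2, d3-d4 and
    e1-e2 to double bonds; demote d2-d3 to single.  Hydrogen counts are
    re-derived from valence on sanitization.  Stereochemistry of the
    input is not propagated to the products.

    Raises
    ------
    SiteRejection
        If the new bond orders violate valence (e.g. a quaternary carbon
        forced into a double bond); the caller continues with remaining
        sites.
    """
    d1, d2, d3, d4 = site.diene_atoms
    e1, e2 = site.dienophile_atoms
    rw = Chem.RWMol(adduct.mol)
    Chem.RemoveStereochemistry(rw)
    try:
        rw.RemoveBond(d1, e1)
        rw.RemoveBond(d4, e2)
        for i, j, order in (
            (d1, d2, Chem.BondType.DOUBLE),
            (d3, d4, Chem.BondType.DOUBLE),
            (e1, e2, Chem.BondType.DOUBLE),
            (d2, d3, Chem.BondType.SINGLE),
        ):
            bond = rw.GetBondBetweenAtoms(i, j)
            if bond is None:
                raise ValueError(f"atoms {i} and {j} are not bonded")
            bond.SetBondType(order)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise SiteRejection(
            f"retro transform at site {site.ring_atoms} rejected: {exc}"
        ) from exc

    frags = Chem.GetMolFrags(product)
    intramolecular = len(frags) == 1
    if intramolecular:
        combined = Chem.MolToSmiles(product)
        diene_smiles = combined
        dienophile_smiles = ""
    else:
        frag_mols = Chem.GetMolFrags(product, asMols=True, sanitizeFrags=True)
        frag_smiles = [Chem.MolToSmiles(m) for m in frag_mols]
        # identify which fragment holds the diene quartet
        diene_frag_idx = next(i for i, atoms in enumerate(frags) if d1 in atoms)
        dienophile_frag_idx = next(i for i, atoms in enumerate(frags) if e1 in atoms)
        diene_smiles = frag_smiles[diene_frag_idx]
        dienophile_smiles = frag_smiles[dienophile_frag_idx]
        combined = ".".join(frag_smiles)
    return RetroProducts(
        diene_smiles=diene_smiles,
        dienophile_smiles=dienophile_smiles,
        combined_smiles=combined,
        intramolecular=intramolecular,
        atom_map={i: i for i in range(product.GetNumAtoms())},  # indices preserved
        product_mol=product,
        site=site,
    )


def forward_check(products: RetroProducts, adduct: Cycloadduct) -> bool:
    """Round-trip validation: re-run the forward cycloaddition on the products.

    Re-forms the d1-e1 and d4-e2 sigma bonds, restores the adduct bond
    orders, and tests graph identity with the adduct (stereochemistry
    ignored).  Returns False on any mismatch.
    """
    site = products.site
    d1, d2, d3, d4 = site.diene_atoms
    e1, e2 = site.dienophile_atoms
    rw = Chem.RWMol(products.product_mol)
    if rw.GetNumAtoms() != adduct.mol.GetNumAtoms():
        return False
    try:
        rw.AddBond(d1, e1, Chem.BondType.SINGLE)
        rw.AddBond(d4, e2, Chem.BondType.SINGLE)
        for i, j, order in (
            (d1, d2, Chem.BondType.SINGLE),
            (d3, d4, Chem.BondType.SINGLE),
            (e1, e2, Chem.BondType.SINGLE),
            (d2, d3, Chem.BondType.DOUBLE),
        ):
            rw.GetBondBetweenAtoms(i, j).SetBondType(order)
        reformed = rw.GetMol()
        Chem.SanitizeMol(reformed)
    except Exception:
        return False
    ref = Chem.Mol(adduct.mol)
    Chem.RemoveStereochemistry(ref)
    Chem.SanitizeMol(ref)
    return Chem.MolToSmiles(reformed) == Chem.MolToSmiles(ref)
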