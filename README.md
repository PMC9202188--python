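# daforge

Automated prediction of Diels–Alder transition-state guess structures
from cycloadduct SMILES, and reaction-force analysis of the resulting
intrinsic reaction coordinate (IRC) paths.

## Who this is for

Computational chemists studying the mechanism of the Diels–Alder (DA)
[4+2] cycloaddition. Locating a transition state (TS) normally needs a
hand-crafted guess geometry per reaction; this package automates the
guess construction for any number of homo-DA reactions starting from
nothing but the SMILES string of each cycloadduct, and then analyzes
the computed reaction paths.

## What it does

**TS-guess chain.** For each cycloadduct the workflow

1. finds every cyclohexene substructure (each one is a competing
   reactive site with four diene-derived carbons d1–d4 and two
   dienophile-derived carbons e1, e2),
2. applies the retro-DA transformation — delete the two σ bonds
   d1–e1 and d4–e2, restore the π systems d1=d2, d3=d4, e1=e2 — giving
   the diene and dienophile (intramolecular cases give one connected
   product),
3. embeds the adduct in 3D and relaxes it with the UFF force field,
   retrying with more conformers (up to 60) and more minimizer runs
   (up to 2000) on failure,
4. builds a constrained optimization that stretches both forming C–C
   bonds to 2.15 Å (configurable), producing a symmetric two-fragment
   *pseudo-guess*: the highest-energy configuration of the scan,
5. writes TS-refinement (eigenvector-following Berny) and frequency
   jobs, keeps only structures with exactly one imaginary frequency,
   and routes rejects to an `ERROR_FILES` folder,
6. writes and parses the IRC job (default ≥ 60 points per direction,
   step 0.8 amu¹ᐟ²·bohr).

All electronic-structure work is delegated to a pluggable text-file
backend: a Gaussian-style dialect for real offline runs, and a
deterministic synthetic backend that lets the whole chain (and the test
suite) run with no QM software at all.

**IRC analysis.** Along a parsed path ξ with energies E(ξ):

- reaction force `F(ξ) = −dE/dξ` and reaction force constant
  `κ(ξ) = d²E/dξ² = −dF/dξ`, by averaged forward/backward finite
  differences;
- synchronicity index `S = | r(d1–e1) − r(d4–e2) |` at the TS (S ≈ 0:
  synchronous mechanism);
- Hellmann–Feynman decomposition: with per-atom forces **F**_A,
  `F(ξ) = Σ_A F_A·(dR_A/dξ)` and `κ(ξ) = Σ_A κ_A(ξ)`; with Cartesian
  Hessians H(ξ) the further split
  `κ = Σ_A κ_AA + 2 Σ_{A<B} κ_AB = κ^atoms + κ^bonds`, where
  `κ_AB = t_Aᵀ H_AB t_B` and
  `κ_AA = t_Aᵀ H_AA t_A − F_A·(d²R_A/dξ²)` with t_A the per-atom path
  tangent. Aggregating κ_A over the two forming-bond pairs shows which
  C–C bond forms first in asynchronous reactions.

## Worked example

`examples/01_retro_diels_alder.py` (see `examples/` for the full set):

```
cyclohexene: C1=CCCCC1  ->  1 reactive site(s)
  site 0: diene atoms (5, 0, 1, 2), dienophile atoms (4, 3)
          retro products: C=CC=C.C=C (two fragments, round-trip ok)
bicyclic (intramolecular): C1=CCCC2CCCCC12  ->  1 reactive site(s)
  site 0: diene atoms (9, 0, 1, 2), dienophile atoms (4, 3)
          retro products: C=CC=CCCCCC=C (intramolecular, round-trip ok)
two competing sites: C1=CC(CCC1)C1CCC=CC1  ->  2 reactive site(s)
```

Cyclohexene splits into butadiene (`C=CC=C`) and ethylene (`C=C`); the
bicyclic adduct opens to a single connected triene because one broken
σ bond is the ring-fusion bond; an adduct with two cyclohexene rings
yields two competing retro pathways, each processed as its own track.
"round-trip ok" means re-running the forward cycloaddition on the
products regenerates the input adduct graph.

`examples/03_reaction_force_profile.py` on a synthetic double-well
path prints

```
F at the TS grid point:      -0.000000 Hartree/xi
kappa at the TS grid point:  -0.249200 Hartree/xi^2 (negative: barrier top)
between the wells: F minimum -0.2397 at xi = -1.40, maximum  0.2397 at xi =  1.40
```

F vanishes at the TS, κ is negative at the barrier top, and the F
extrema bracket the bond-reorganization region.

## Command line

```
daforge run --config da.ini            # TS-prediction pipeline
daforge analyze --config da.ini --analysis analysis.ini
daforge fixtures --out fixtures/       # synthetic IRC fixture files
```

`da.ini` holds the SMILES file, workdir, theory levels (defaults PM6
for the guess, B3LYP/6-31G(d) for refinement), the 2.15 Å separation,
IRC settings and the `RC_FLAG`/`RFA_FLAG`/`RFD_FLAG` stage gates;
`analysis.ini` selects systems and atoms for the decomposition. See
`src/daforge/config.py` for the full keyword set.

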