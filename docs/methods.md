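# Methods

## Scope and model

The package automates two connected tasks for homo-Diels–Alder (DA)
reactions: constructing transition-state (TS) guess structures from
cycloadduct SMILES, and analyzing discretized intrinsic reaction
coordinate (IRC) paths with the reaction-force formalism. Electronic
structure itself is out of scope: the package writes job files and
parses outputs in a Gaussian-style text dialect, and ships a synthetic
backend so that every stage is executable and testable without any
quantum-chemistry engine.

## Reactive-site model

A DA cycloadduct is recognised by its cyclohexene substructure: a
six-membered, all-carbon, non-aromatic ring with exactly one endocyclic
double bond. Writing the ring cyclically as d1–d2=d3–d4–e2–e1, the
partition into diene-derived (d1–d4) and dienophile-derived (e1, e2)
atoms is fixed by the double-bond position: the alkene carbons and
their ring neighbours came from the diene, the remaining two ring atoms
from the dienophile. This is the only partition consistent with the
retro bookkeeping (delete d1–e1 and d4–e2; promote d1–d2, d3–d4, e1–e2
to double; demote d2–d3 to single). Orientation of the traversal is
canonicalized by taking d2 as the smaller-index alkene carbon; both
orientations name the same bonds, so the site is unique. Rings whose
double bond is aromatic are excluded (aromatic bonds are not DA-formed
alkenes), duplicate matches of the same six atoms collapse to one site,
and atom indexing is 0-based internally (job files use the dialect's
1-based indices).

Every retro result is validated by re-running the forward
cycloaddition on the product graph and requiring isomorphism with the
input adduct; stereochemistry is recorded on the adduct but not
propagated to retro products. For neutral all-carbon adducts the
bookkeeping is always valence-consistent (each atom gaining a π bond
loses a σ bond), so the site-rejection path guards against malformed or
hand-edited sites rather than ordinary inputs.

## Geometry preparation

3D structures come from distance-geometry embedding (ETKDGv3) followed
by UFF relaxation. UFF is non-reactive, so the bond graph is conserved
by construction; it also has parameters for nearly the whole periodic
table, so exotic substituents do not abort the pipeline. The retry
schedule is two-stage: 10 conformers / 200 minimizer iterations first,
then the caps of 60 conformers / 2000 iterations. Among converged
conformers the lowest force-field energy wins. The embedding seed
defaults to 42, is configurable, and is recorded in the state file;
identical seeds give identical coordinates.

The pseudo-guess is specified as two frozen distance constraints
holding the forming bonds (d1–e1) and (d4–e2) at 2.15 Å (user
configurable). The highest-energy configuration of the constrained
scan is taken as the pseudo-guess; energy ties break toward the later
scan index, i.e. the more stretched configuration. The default scan
granularity is 16 configurations, matching common backend behaviour;
it is a config option, not a contract.

## Job dialect and parsing

Job inputs are Gaussian-style: a route line per stage
(`opt=modredundant` with `B i j target F` constraint records;
`opt=(ts,berny,calcfc,noeigen) freq` for saddle searches;
`irc=(maxpoints=N,stepsize=S,calcfc,both)` where S is an integer in
units of 0.01 amu¹ᐟ²·bohr, so 0.8 → 80). Output parsing keys on the
dialect's landmarks (`Input orientation:`, `SCF Done:`,
`Frequencies --`, IRC point blocks with direction and net reaction
coordinate, `Forces (Hartrees/Bohr)` tables, a termination trailer).
Failure detection happens at parse time against a config-extensible
list of diagnostic substrings plus a missing-terminator check. The
package also defines a plain-text path format (`*.ircpath`: header
with atom/point counts, then per point ξ, E and per-atom
element/x/y/z[/fx/fy/fz] rows) used to store parsed paths and by the
fixture generator; round trips are exact to the printed precision
(1e-9).

IRC direction convention: negative ξ is the reactant side, positive
the product side, TS at ξ = 0. The duplicate TS record emitted by
two-direction runs is deduplicated; points are returned sorted with a
strictly increasing grid. Paths without force tables are flagged, and
the decomposition cleanly refuses them while the total profiles remain
available.

A stationary point is accepted as a TS iff its frequency set contains
exactly one imaginary (negative) mode; zero marks a minimum, two or
more a higher-order saddle. Rejected files are *copied* (never moved)
into `ERROR_FILES` with collision-safe names and a `manifest.tsv` row
(filename, stage, reason).

## Reaction-force analysis

With E(ξ) sampled on the IRC grid, F(ξ) = −dE/dξ and
κ(ξ) = d²E/dξ² = −dF/dξ. Differentiation uses the average of the
forward and backward one-sided slopes at interior points and the
single available slope at the endpoints. On a uniform grid the
averaged rule is the central difference: exact for quadratics at
interior points, O(h²) generally, O(h) at the endpoints. The rule is
applied verbatim on non-uniform grids as well, even though a weighted
central difference would be formally more accurate there — fidelity to
the simple averaged scheme is preferred, and all shipped grids are
uniform. NaN energies abort the profile rather than being
interpolated. The TS point receives no special casing.

Units are Hartree and amu¹ᐟ²·bohr internally; reports may convert the
energy scale by the factor 627.5094740631 kcal/mol per Hartree. Every
TSV output states its units in a header line.

## Atomic decomposition

Using per-atom (Hellmann–Feynman) forces **F**_A in Hartree/bohr and
per-atom path tangents t_A = dR_A/dξ (coordinates converted Å → bohr),
the projected contribution F_A(ξ) = **F**_A·t_A sums to the total
force, and κ_A = −d(F_A)/dξ sums to κ. Tangents, and the second
derivatives d²R_A/dξ² needed below, use the same averaged difference
scheme (applied twice for the second derivative).

When Cartesian Hessians H(ξ) are available, κ splits into
κ_AB = t_Aᵀ H_AB t_B (A ≠ B) and
κ_AA = t_Aᵀ H_AA t_A − **F**_A·(d²R_A/dξ²), with
κ^atoms = Σ_A κ_AA and κ^bonds = 2 Σ_{A<B} κ_AB summing to κ. How the
Hessians are obtained is left to the user: they are optional inputs
(synthetic, or parsed from frequency-type outputs), and without them
the per-atom κ_A decomposition still runs. Endpoint values of the
split involve one-sided second derivatives and are excluded from
reports.

Sign bookkeeping is fixed once: forces are negative energy gradients,
F from the first derivative with a minus sign, κ = −dF/dξ; under this
convention the two printed forms of κ (d²E/dξ² and −dF/dξ) coincide,
and all conservation identities are tested against it.

Conservation tolerances: on self-consistent synthetic paths the summed
atomic contributions reproduce the totals within 1e-3 relative,
evaluated at interior points — one point in from each end for F (first
derivative), two points for κ and the atoms/bonds split (second
derivatives), since the one-sided endpoint stencils are O(h) and would
otherwise dominate the comparison. The residual is pure truncation
error and shrinks ~quadratically with the step (verified empirically).

## Synthetic fixtures

The generator produces paths whose energies, geometries, forces and
Hessians are *exactly* mutually consistent, so conservation tests have
an exact target. E(ξ) is an inverted parabola, a quartic double well
a·ξ⁴ − b·ξ² (+ c·ξ³ for asymmetric, "asynchronous-like" profiles), or
a raw polynomial; defaults a = 0.01, b = 0.125 put the two wells at
ξ = ±2.5 with the barrier top at ξ = 0, mimicking the shape of a
reaction profile at the scale of the default grids. Atom trajectories
are base + linear·ξ + amp·sin(freq·ξ + phase) with seeded parameters;
one force component (the last atom's x channel, whose tangent is
pinned to a nonzero constant) is solved point-by-point so that
Σ_A **F**_A·t_A = −dE/dξ holds to machine precision. Hessians start
from a seeded random symmetric matrix and receive a rank-one
correction along the exact path tangent so the curvature of E along
the path is reproduced exactly. Generation is a pure function of
(spec, seed).

These fixtures are mathematical, not chemical: they exercise the
numerics and the parsers, not DA energetics. Passing tests therefore
demonstrate correctness of the differentiation, decomposition and I/O
machinery, and of the pipeline logic — not the accuracy of any quantum
chemistry, which belongs to the external backend.

The synthetic *backend* extends the same idea to the pipeline stages:
scans interpolate the constrained distances toward their targets with
rising energies, TS optimizations place the forming bonds at
prescribed distances (equal by default, hence synchronicity index 0;
unequal to emulate asynchronous cases), frequency sections carry one
imaginary mode unless a failure is injected, and IRC outputs move the
dienophile-side atoms along the forming-bond axes over an inverted
parabola with exactly consistent forces.

## Pipeline engineering

Each (adduct, site) pair is an independent track; exceptions are
contained per track and recorded with a reason. State persists as JSON
per workdir; re-running skips tracks already at a terminal stage, so
restarts are idempotent at track granularity. Analyses are gated by
`RFA_FLAG`/`RFD_FLAG` (requests with the flag unset are ignored with a
notice), and `RC_FLAG` additionally emits reactant-optimization job
files for the retro products. Exit codes: 0 when at least one system
reaches its requested terminal stage, 1 on total failure, 2 on
configuration errors.

Default problem sizes in the shipped tests and the acceptance script
(fixture adducts up to 12 heavy atoms, IRC grids of 11–101 points) are
chosen so every numeric claim is checked at truncation errors well
below the stated tolerances while the whole suite runs in seconds.

## Known limitations

- Homo-DA only: rings containing heteroatoms at reactive positions are
  not matched.
- No regio-/stereoselectivity prediction; stereochemistry is dropped in
  retro products.
- The reaction-region partition of the IRC from the F extrema is not
  implemented.
- The atoms/bonds split requires externally supplied Hessians; the
  package never derives forces or Hessians from wavefunctions.
- Restart granularity is per track, not per stage within a track.
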