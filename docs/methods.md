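# Methods

`epiface` characterizes antibody–antigen (Ab–Ag) binding interfaces from
PDB structures of the complex. The two molecules are treated as rigid
bodies extracted from the complexed structure: no conformational
rearrangement is modelled anywhere in the pipeline.

## Burial-based interface definition

Solvent exposure is computed by a deterministic numerical accessibility
engine. Every heavy atom carries a van der Waals radius by element
(C 1.70, N 1.55, O 1.52, S 1.80 Å); its solvent-expanded sphere
(radius *r* + *R*probe) is sampled at `n_points` golden-spiral directions
(default 960), and a sample point is accessible when it lies outside every
neighbour's expanded sphere. An atom is *exposed* when at least one point
is accessible; its area is the accessible fraction of 4π(*r*+*R*)².
The point set has a fixed orientation in space, so results are
bit-reproducible; the suite verifies the engine against closed-form
isolated-sphere and two-sphere areas (within 2% at 960 points), against
an independent Shrake–Rupley implementation, and for <1% drift when the
point count doubles.

An atom is *interfacial* when it is exposed in its monomer and loses all
exposure in the complex; a residue is interfacial when it owns at least
one interfacial atom. The epitope is the interfacial residue set of the
antigen, the paratope that of the antibody, and the interface area is
A(Ab) + A(Ag) − A(complex). Because the complex contains a superset of
each monomer's atoms and the sample directions are shared, per-atom buried
areas are non-negative and the set difference is exact, not a numerical
artifact.

The original exposed-atom bookkeeping this replaces was done on a
solvent-excluded surface (SES). The exposure *criterion* is the same —
an atom touches the SES exactly when its solvent-expanded sphere has
accessible points — so exposed-atom sets and hence all epitope/paratope
sets coincide; only areas differ, by roughly 5% on real proteins. An
optional `calibration` factor (default 1.0; 0.95 approximates an SES
accounting) rescales reported areas. A cavity-reachability analysis is
deliberately not performed: interior voids count as accessible space,
consistent with the pointwise accessibility criterion.

## Sub-epitope set algebra

The burial computation is re-run on reduced systems — antigen plus one
CDR, plus all CDRs, plus one antibody chain, plus the framework only —
and the resulting epitopes are combined set-theoretically:

* per-CDR epitopes and their pairwise intersections (shared residues);
* chain epitopes, whose complement within the full epitope is the
  inter-chain cavity term;
* the all-CDR epitope minus the union of single-CDR epitopes is the
  inter-CDR cavity term;
* the framework-only epitope;
* the full epitope minus the single-CDR union is the extra-CDR set, and
  what remains of it after removing framework, inter-CDR and inter-chain
  members is attributed to joint CDR–framework burial.

CDR intervals follow the Chothia convention (H1 26–32, H2 52–56,
H3 95–102, L1 24–34, L2 50–56, L3 89–97), configurable via
`RegionScheme`; insertion-coded residues inherit the interval of their
base number. The framework-only system keeps every non-CDR antibody
residue present in the file, constant domains included. All identities
are pure set algebra and are asserted exactly in the tests.

## Exposedness classes

Antigen exposure is evaluated at three probe radii: 1.4 Å (water), 9 Å
(approximately a CDR loop), and 100 Å (quasi convex hull). Epitope
residues reachable only by the water probe are *deep*, those reachable by
the 9 Å probe *medium*, and those still exposed to the 100 Å probe
*superficial*. Exact geometry guarantees the exposed sets nest as the
probe grows; the implementation additionally intersects each larger-probe
set with the previous one so that sampling noise can never violate the
nesting. Because the accessible cone of a large probe is narrow, this
profile uses a denser point set (default 4000) than the burial step.

## Surface patches and linear stretches

The epitope contact surface is split into connected components over an
atom graph: nodes are interfacial epitope atoms within 4 Å of any
interfacial paratope atom (pruning), and two nodes are adjacent when
their solvent-expanded spheres overlap (center distance ≤
r₁ + r₂ + 2·probe), i.e. when they share contiguous accessible surface.
This approximates mesh connectivity without triangulation. Component
areas are buried-area sums; components below 5% of the total are
discarded. Patch counts are rigid-motion invariant; the area *split* can
drift by a fraction of a percent under rotation because per-atom areas
are sampled on a space-fixed point set.

Linear stretches are maximal epitope runs along each antigen chain with
at most `gap_tolerance` (default 1) non-epitope sequence positions
between consecutive members; chains are never bridged, numbering gaps
from unresolved residues count at their numeric size, and stretch length
counts epitope residues only (tolerated gaps are not counted — the
counting basis is a package choice).

Secondary-structure composition is read from standard DSSP files
(helix = {H,G,I}, strand = {E,B}, coil = everything else); residues
missing from the file count as coil with a warning.

## Hydrophobic cluster protocol

Cross-interface carbon pairs closer than `cc_dist` (default 5 Å; results
are insensitive in the 4–5 Å range, which the suite checks on fixtures
with 3.8 Å planted separations) are candidate contacts. A candidate is
rejected when an O/N atom sits geometrically between the carbons:

1. d₁ = û(Cp→Ce)·û(Cp→P). d₁ < 0.85 clears P (off-axis).
2. otherwise d₂ = û(Cp→Ce)·û(Ce→P). d₂ < −0.2 confirms shielding;
   larger values mean P is behind the epitope carbon and the pair stays
   clear.

Vectors are normalized before the dot products (the thresholds are
cosines). Polar candidates are all O/N atoms of either molecule,
backbone and side chain alike, within `polar_search_dist` (default 5 Å)
of either carbon; they are tried nearest-to-midpoint first so the
recorded shielder is deterministic. Sulfur neither joins clusters nor
shields. Cleared pairs are edges of an undirected graph; connected
components are the hydrophobic clusters, ordered by size with ties broken
by lowest atom serial. Shielding rejections are attributed to the polar
atom responsible and feed the polar-role classification.

## Polar and ring interactions

Hydrogen bonds use a heavy-atom criterion: donor/acceptor-compatible
cross-interface pairs within 3.9 Å. Hydrogens are absent from the model,
so no angular term is evaluated — this is the declared approximation, and
the threshold is configurable. The donor/acceptor table: backbone N
donates (except proline), backbone O accepts, Ser/Thr/Tyr hydroxyls do
both, Asn/Gln amides donate from N and accept on O, His ring nitrogens do
both, Trp NE1 donates, Arg/Lys nitrogens donate, Asp/Glu carboxylates
accept; Cys SG is excluded. Salt bridges are the subset between
side-chain cationic nitrogens (Arg NE/NH1/NH2, Lys NZ) and side-chain
anionic oxygens (Asp OD1/OD2, Glu OE1/OE2); His is neither cationic nor
anionic. A qualifying pair is reported once, as a salt bridge. A
crystallographic water within 3.9 Å of polar atoms on both sides mediates
a water bridge; one record per (water, Ab atom, Ag atom) triple plus a
per-water count. Structures without waters are flagged rather than
reported as zero.

Aromatic rings (Phe/Tyr 6-ring, His 5-ring, Trp as one 9-atom system)
get a centroid and a least-squares plane normal (smallest principal axis
of the centered ring coordinates; sign-free, all criteria use absolute
dots). Parallel stacking: centroids closer than 5 Å and |n̂₁·n̂₂| > 0.85.
Ring–ion: ion within 5 Å of the centroid and |û(centroid→ion)·n̂| > 0.70,
typed by the ion's sign; only cross-interface pairs count, and His is an
aromatic partner but never an ion.

Each interfacial polar atom is classified by role — polar bond,
shielding, both, or none — with fractions per (molecule × backbone/side
chain) stratum, and Tyr/Trp/Phe/Ser interface residues get per-residue
role sets combining cluster membership with every interaction type.

## Interface charges

Titratable side chains (Asp, Glu, His, Cys, Tyr, Lys, and Arg as a
near-fully-charged base) contribute fractional Henderson–Hasselbalch
charges: −1/(1+10^(pKa−pH)) for acids, +1/(1+10^(pH−pKa)) for bases.
Per-site pKa values are ingested from a CSV table (chain, resnum, icode,
site, pKa), typically produced by a continuum-electrostatics tool; sites
without an entry fall back to reference values measured on capped
alanine pentapeptides (Asp 3.9, Glu 4.3, His 6.5, Cys 8.6, Tyr 9.8,
Lys 10.4, Arg 12.3). Termini are excluded. Net charges are evaluated at
pH 7.2 by default; the complementarity class (opposite / same /
one-neutral / both-neutral) uses charges rounded to the nearest integer.
Fractional charges rather than discrete protonation states are a package
choice; rounding is applied only for the class label.

## Synthetic complexes with planted truth

The generator emits PDB files plus JSON manifests naming every expected
outcome, so the full pipeline is testable without any downloaded data.

The slab fixture places an antigen island of residues on a 4 Å grid:
each island residue has a facing carbon at z = 0 over a backbone stack,
and the antibody seals it from directly above (carbon at z = gap,
default 4 Å) with four lateral prong carbons per residue and an upper
blocker, so that every island residue — and provably no rim residue —
loses all exposure in the complex. A one-cell rim of single-atom support
residues closes lateral channels while staying exposed itself. The
planted epitope is exactly the island; the planted paratope core is the
facing residues over island cells (rim-covering residues are usually
buried too but depend on single-atom support, so they are not asserted).
The facing carbons and prongs form a single connected cross-interface
carbon graph whose membership the generator derives by exhaustive
union-find and stores in the manifest. Antibody residues carry genuine
Chothia numbering (H3 by default, optionally spread over H1/H2/H3,
framework-only, with insertion codes exercised on overflow).

Seam fixtures omit the antibody residue over the center cell of a 3×3
island and let the four neighbours' prongs seal it jointly; assigning the
neighbours to two chains (or to two CDRs of one chain) plants a residue
that is buried only in the full complex — the ground truth for the
inter-chain and inter-CDR cavity terms.

Interaction plants sit on isolated sites 20 Å apart beside the slab:
carbon pairs at 4.0 Å, shielded pairs with an oxygen at the exact
midpoint, hydrogen bonds at 2.9 Å, Lys–Glu salt bridges at 3.0 Å, water
bridges at 2.8/3.0 Å, parallel Phe stacks at 3.8 Å, and on-axis ring
ions at 4.0 Å — with decoys at super-threshold distances or failing
angles. A pocket antigen (spherical shell with an axial invagination)
plants deep/superficial exposedness classes, and a zigzag carbon chain
with all contact distances at 3.8 Å exercises threshold robustness.

Coordinates get a small uniform jitter (±0.02 Å, seeded) except for
threshold-critical planted atoms; output is byte-identical per seed.
What the fixtures do **not** emulate: realistic side-chain rotamers,
packing densities, crystallographic disorder, or HBPLUS-style angular
hydrogen-bond geometry — so passing tests certify the geometric
criteria and set algebra, not agreement with real-corpus statistics.

## Pipeline and aggregation

`run_complex` executes everything in dependency order and degrades
gracefully (a structure without waters yields no water-mediated count,
flagged; a failing complex in a manifest run is logged and skipped).
Optional filters reproduce corpus curation: maximum resolution and
minimum antigen length (≥50 residues). Hydrophobic clustering runs on
the carbons of epitope/paratope residues; polar and ring detection runs
over all heavy atoms of both molecules, since the distance criteria bound
the search themselves; role classification is restricted to interface
polar atoms. Aggregation reports unweighted per-complex means with the
population standard deviation (a singleton aggregates to sd 0) and pools
amino-acid compositions over residues. Each (heavy, light, antigen)
pairing in a manifest row is an independent complex.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on 3×3 to 6×6 slabs
(≈400–900 atoms), 20 planted-interaction panels, and ~170-atom pocket
shells; burial uses 960 sphere points and the exposedness profile 4000.
These sizes give sub-second to few-second per-complex runtimes while
keeping every planted margin several sampling widths wide. Degenerate
inputs are defined: empty epitopes flag the exposedness profile as
undefined, coincident atom centers warn and retain both atoms,
zero-length shielding vectors reject the pair, incomplete rings are
skipped with a warning, and empty CDR subsets yield empty epitope sets.

## Known limitations

* Hydrogen-bond detection is distance-plus-typing only; counts on real
  structures will differ slightly from angle-aware assignments.
* Patch areas are buried-SASA sums, not triangulated mesh areas;
  area *fractions* are the comparable quantity.
* pKa values are taken as given (or pentapeptide references); no
  electrostatics is computed and sites titrate independently.
* The numbering must already be Chothia; no renumbering is performed,
  and mmCIF input is not supported.
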