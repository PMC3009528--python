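# Methods

## Standardization model

MHC class II binding domains are strongly conserved in fold and length, so
"structurally equivalent positions" across complexes are realized here by
**global sequence alignment** (match +1, mismatch 0, gap −1; configurable)
of each chain against packaged α1/β1 reference profiles, not by structure
superposition-based equivalencing. This is deterministic, dependency-free
and adequate for the essentially gap-free binding domains the tool
targets; a structure-based fallback is deliberately out of scope. An
alignment identity below 30% only flags the result (the chains a user
feeds in are homologous by construction); fewer than 50% of reference
domain positions mapped is an error.

After renumbering (α1 → 5–78, β1 → 5–91), the complex is superposed onto
the reference frame by a Kabsch least-squares fit over all mapped Cα pairs
of both domains jointly; the returned rotation is always proper
(det = +1). Peptide residues are then assigned to the 13 harmonized
positions 308–320 by nearest reference-peptide Cα (cutoff 8 Å), with the
assignment required to be injective and sequence-order consistent; among
maximum-cardinality monotone assignments the one with the smallest total
Cα distance is chosen by dynamic programming. This handles engineered
peptides fused to an MHC chain (given a residue range) and peptides longer
than 13 residues (extras are trimmed). Anchors sit at P1 = 308, P4 = 311,
P6 = 313, P7 = 314, P9 = 316.

The packaged reference frame is **synthetic**: a deterministic groove-like
complex produced by the fixture generator (fixed sequences, fixed
geometry), frozen to `data/reference_frame_synthetic.txt`. A reference
frame only has to be fixed and self-consistent to anchor numbering and
superposition; shipping a synthetic one keeps the package self-contained
and avoids misrepresenting experimental coordinates. Users comparing real
crystal structures get identical scores whatever frame is used, because
the descriptor is rigid-motion invariant; only the cosmetic common frame
of the written PDB files depends on it.

## Atom typing

Heavy atoms plus their implicit hydrogens are united groups typed by
element, total covalent connectivity and hydrogen count — 13 types over
the 20 standard amino acids — with ProtOr united-group radii (C3H0 1.61,
C3H1 1.76, C4H1/C4H2/C4H3 1.88, all N 1.64, O1H0 1.42, O2H1 1.46, S 1.77 Å).
Protonation-ambiguous atoms get a single fixed assignment for determinism:
HIS ND1 = N3H1, NE2 = N3H0 (one tautomer), carboxylate oxygens of Asp/Glu
O1H0 (ionized), C-terminal OXT O2H1, N-terminal nitrogens typed as the
residue's backbone N. MSE is aliased to MET; other nonstandard residues
raise a typing error (or are skipped under the lenient flag — atoms may be
dropped, never mistyped). The full table is a plain-text asset users can
audit or extend.

## Accessibility and pocket extraction

SASA uses the Shrake–Rupley scheme with a deterministic generalized-spiral
(golden-angle) point set — no random quadrature, so results are exactly
reproducible and regression-testable. Defaults: probe 1.4 Å (water),
960 points/atom, both exposed. 960 points puts the isolated-atom error
well below 0.5% and the two-sphere error below 1% of the analytic
closed forms (checked in the test suite and the acceptance script).

A groove/sub-pocket atom is one whose SASA *decreases by more than
epsilon* when the occluder is added. The strict reading "decreases"
would be quadrature-noise sensitive, so epsilon defaults to a small
positive 0.1 Å² and is exposed as a flag. Two further choices the
occlusion definition leaves open were fixed as follows: the sub-pocket
occluder is the complete crystallized residue (backbone + side chain, no
alanine truncation — truncated views are a visualization device, not part
of extraction), and the SASA context for a sub-pocket excludes the other
12 peptide residues, i.e. the literal "presence of the peptide residue at
position Pk". Both choices make every sub-pocket a subset of the whole
groove at equal epsilon (monotone occlusion), which is asserted as an
invariant. Pockets with fewer than 3 atoms are extraction errors, never
silently scored.

For speed, adding an occluder only re-evaluates MHC atoms whose expanded
sphere can overlap an occluder expanded sphere; the peptide-free SASA is
computed once and shared across the whole groove and all five sub-pockets.

## Descriptor and scoring

Distances are stored at full float precision; no rounding before
matching. The match criterion is inclusive (|da − db| ≤ t, Å). The greedy
two-pointer sweep was chosen as the list-alignment step and is *verified*
(not assumed) optimal: a property test compares it to an exact
maximum-bipartite-matching oracle over 1000 random sorted list pairs at
thresholds 0.125–1.0 Å. Matches are summed over the 91 lists before
dividing (the cumulative reading), rather than averaging per-bin ratios.
Comparing an empty or undersized pocket is an error, not a score — an
empty pocket means upstream extraction failed. PMSMin ≤ PMSMax always,
with equality exactly when the two sites have equal distance counts.

## Clustering

Neighbour joining is implemented directly (Saitou–Nei) rather than
wrapping an external program, with an explicit deterministic tie-break
(lowest label index pair) and negative branch lengths clamped to zero
with the deficit logged. Runs that fed other NJ implementations in a
particular input order can therefore differ in tie cases; exact tree-shape
replication there is not promised. On exactly additive matrices the
generating topology and branch lengths are recovered to machine precision
(tested on the 4-taxon worked example). Histograms use ten bins of width
0.1 with the top bin closed ([0.9, 1.0]), so a perfect score is counted.

## Sensitivity analysis

Geometric perturbation adds i.i.d. Gaussian displacements rescaled so the
in-frame RMSD (no re-superposition) hits the target exactly; target RMSDs
are sampled uniformly on (0, max] with max 5 Å by default. Chemical
perturbation re-assigns a chosen fraction of atoms to uniformly random
*different* group types, coordinates untouched. The two perturbations are
complementary by construction: geometry-only moves change distance values
but never bin occupancies; relabelling changes occupancies but preserves
the pooled distance multiset. Everything is seeded and reproducible
end-to-end. The default ensemble size is 1000 members; tests and the
acceptance script run a 200-member ensemble on a 40-atom pocket, which is
ample to resolve the monotone decay of binned mean scores with RMSD and
the pointwise dominance of larger thresholds.

## Synthetic data: what it does and does not show

The fixture generator emulates the *topology* of a class II complex — two
long chains flanking a 13-residue peptide, with peptide side chains
pointing into the cleft so occlusion-based extraction finds a groove and
five sub-pockets — plus multi-copy asymmetric units, over-long peptides,
displaced peptides, and optional coordinate jitter. Residues carry only
N/CA/C/O/CB atoms on a schematic serpentine path; the geometry is not
physically realistic (no secondary structure, no full side chains, no
packing). Passing tests therefore demonstrate the correctness of the
pipeline's logic and numerics, and the qualitative behaviour of the
score, on groove-shaped inputs; they do not certify score values on real
crystal structures, which additionally stress missing atoms, alternate
conformations and nonstandard residues (each handled, but exercised here
only in isolation).

## Known limitations

- Sequence-based (not structure-based) position equivalencing; unusual
  insertions near the groove would mis-map.
- Single fixed protonation/tautomer assignments; no explicit hydrogens.
- Approximate (quadrature) SASA, not analytic; membership of atoms whose
  occlusion is within ~epsilon of the threshold can flip with the point
  count (observed: <1% of atoms when doubling 960 → 1920).
- Cofactors/ligands other than the peptide are excluded from SASA
  contexts; mmCIF input and MHC class I are out of scope.
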