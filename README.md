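# pm13 — comparing MHC class II binding grooves and sub-pockets

`pm13` is a library and command-line tool for alignment-free, quantitative
comparison of the peptide-binding grooves of MHC class II molecules from
their three-dimensional structures. It is aimed at structural
immunologists who want to classify alleles by binding-site similarity,
spot intra-allelic conformational differences, or relate sub-pocket
variation to peptide-binding specificity — without superposing every pair
of structures by hand.

## The method

An MHC class II binding domain (α1 + β1, with a bound peptide) is first
**standardized**: chains are relabelled A/B/C, α1 residues renumbered to
reference positions 5–78 and β1 residues to 5–91, the complex is
rigid-body superposed (Kabsch) onto a packaged reference frame, and the
peptide is trimmed/renumbered to 13 harmonized positions 308–320 with the
anchor sub-pockets at P1 = 308, P4 = 311, P6 = 313, P7 = 314, P9 = 316.

The **binding groove** is defined by occlusion: an MHC atom belongs to
the groove iff its solvent-accessible surface area (Shrake–Rupley, probe
radius 1.4 Å, ProtOr united-group radii) decreases when the peptide is
present. Each sub-pocket uses the single peptide residue at the mapped
position as occluder instead of the whole peptide.

Each pocket of *n* typed atoms is summarized by its *n(n−1)/2* intra-site
distances, partitioned by the unordered pair of ProtOr group types of the
endpoints (13 types → 13·12/2 + 13 = **91 sorted distance lists**), a
rigid-motion-invariant shape+chemistry descriptor. Two pockets are scored
by sweeping corresponding lists with a greedy two-pointer alignment: a
pair of distances matches if it differs by at most a threshold *t*
(default 0.5 Å), each element matching at most once (the sweep is exactly
optimal on sorted lists — property-tested against a maximum-bipartite-
matching oracle). With *M* the cumulative match count over the 91 lists,

    PMSMin = M / (# distances in the larger site)
    PMSMax = M / (# distances in the smaller site)

and the headline **PM13 score is PMSMin** (1.0 = indistinguishable at
threshold *t*). Score matrices are converted to distances d = 1 − PM13
and clustered with Saitou–Nei neighbour joining into Newick cladograms;
a sensitivity module quantifies score decay under controlled coordinate
perturbation (exact target RMSD) and random re-assignment of group types.

## Worked example

No crystal structures at hand? The `fixtures` module generates small,
valid synthetic groove complexes so the whole pipeline can be exercised:

```python
from pathlib import Path
from pm13 import (FixtureSpec, make_complex_pdb, parse_structure,
                  identify_complexes, standardize_complex, compare_pockets)
from pm13.accessibility import extract_pockets

workdir = Path("demo"); workdir.mkdir(exist_ok=True)
pockets = {}
for seed, jitter in ((0, 0.0), (1, 0.3)):
    pdb = make_complex_pdb(FixtureSpec(seed=seed, jitter=jitter),
                           workdir / f"complex{seed}.pdb")
    raw = parse_structure(pdb)
    spec = identify_complexes(raw)[0]          # finds chains A/B/C
    sc = standardize_complex(raw, spec)        # renumber + superpose
    pockets[seed] = extract_pockets(sc)        # whole groove + P1..P9

whole0 = pockets[0]["whole"]
print(f"groove of complex 0: {len(whole0)} atoms")
for kind in ("whole", "P1", "P4", "P6", "P7", "P9"):
    s = compare_pockets(pockets[0][kind], pockets[1][kind])
    print(f"{kind:>5}:  PMSMin {s.pms_min:.2f}   PMSMax {s.pms_max:.2f}")
```

which prints:

```
groove of complex 0: 67 atoms
whole:  PMSMin 0.70   PMSMax 0.88
   P1:  PMSMin 0.36   PMSMax 0.67
   P4:  PMSMin 0.69   PMSMax 0.91
   P6:  PMSMin 0.36   PMSMax 0.62
   P7:  PMSMin 0.53   PMSMax 0.78
   P9:  PMSMin 0.45   PMSMax 0.69
```

The two complexes share the same fold but the second carries 0.3 Å of
coordinate noise: the whole grooves still match well (0.70), while the
small sub-pockets — fewer atoms, so each displaced distance costs more —
spread over a wider score range, exactly the behaviour used to localize
differences between alleles to individual pockets.

The same workflow from the shell:

```bash
pm13 fixtures make -o demo --n 3
pm13 run demo/*.pdb -o out            # standardize, pockets, matrices, trees
cat out/scores-whole.tsv              # PM13 score matrix
cat out/tree-P4.nwk                   # NJ cladogram of P4 sub-pockets
```

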