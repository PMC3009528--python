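"""Solvent accessibility and occlusion-based pocket definitions.

Per-atom solvent-accessible surface area (SASA) is computed with the
Shrake–Rupley scheme: each atom's sphere is expanded by the probe radius
(1.4 Å by default), covered with a deterministic quasi-uniform point set,
and the accessible fraction is the fraction of points not buried inside
any neighbouring expanded sphere. ProtOr united-group radii stand in for
van der Waals radii, so attached hydrogens are implicit.

Pockets are then defined by occlusion: an MHC atom belongs to the binding
groove iff its SASA drops (by more than a small threshold ``epsilon``)
when the peptide is added to the context; the P1/P4/P6/P7/P9 sub-pockets
use the single peptide residue at the corresponding harmonized position
(308/311/313/314/316) as the occluder instead of the whole peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atom_typing import TypedAtom, type_atom
from .errors import ExtractionError, InputError, MissingResidueError, TypingError
from .structure_io import SUBPOCKET_POSITIONS, Residue, StandardComplex

POCKET_KINDS = ("whole", "P1", "P4", "P6", "P7", "P9")

DEFAULT_PROBE = 1.4      # Å, water-sized probe sphere
DEFAULT_N_POINTS = 960   # quadrature points per atom
DEFAULT_EPSILON = 0.1    # Å², minimum SASA loss to count as occluded


@dataclass
class SasaResult:
    areas: np.ndarray          # Å² per atom, same order as the input
    probe: float
    n_points: int


@dataclass
class Pocket:
    """A typed point cloud: the whole groove or one sub-pocket."""

    kind: str
    atoms: list[TypedAtom]
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def groups(self) -> list[str]:
        return [a.group for a in self.atoms]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (generalized golden spiral)."""
    if n < 16:
        raise InputError(f"need at least 16 sample points, got {n}")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i          # golden-angle longitudes
    z = 1.0 - (2.0 * i + 1.0) / n                   # uniform latitudes
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def compute_sasa(atoms: list[TypedAtom], probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 subset: list[int] | None = None) -> SasaResult:
    """Shrake–Rupley per-atom SASA with ProtOr radii.

    For each atom the fraction of its expanded-sphere (r + probe) sample
    points outside every other expanded sphere is multiplied by the full
    expanded-sphere area 4π(r + probe)². With ``subset``, areas are only
    computed for the given atom indices (the rest are NaN); every atom
    still acts as an occluder.
    """
    if not atoms:
        raise InputError("compute_sasa needs at least one atom")
    coords = np.array([a.xyz for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.full(len(atoms), np.nan)
    for i in (range(len(atoms)) if subset is None else subset):
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                 if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        pts = coords[i] + radii[i] * unit
        free = np.ones(n_points, dtype=bool)
        for j in neigh:
            free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not free.any():
                break
        areas[i] = free.mean() * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(areas, probe, n_points)


# ---------------------------------------------------------------------------
# pocket extraction

def typed_atoms(residues: list[Residue], chain: str, *,
                lenient: bool = False) -> list[TypedAtom]:
    """ProtOr-type every heavy atom of the given residues.

    Under ``lenient`` unknown (residue, atom) pairs are skipped instead of
    raising; atoms are never mistyped.
    """
    out = []
    for r in residues:
        for a in r.atoms:
            try:
                out.append(type_atom(r.name, a.name, a.x, a.y, a.z,
                                     chain=chain, res_seq=r.seq))
            except TypingError:
                if not lenient:
                    raise
    return out


def _occluded(mhc: list[TypedAtom], occluder: list[TypedAtom], epsilon: float,
              probe: float, n_points: int,
              alone: np.ndarray | None = None) -> list[TypedAtom]:
    if alone is None:
        alone = compute_sasa(mhc, probe, n_points).areas
    # adding occluder atoms can only change the SASA of MHC atoms whose
    # expanded sphere overlaps an occluder expanded sphere
    occ_coords = np.array([a.xyz for a in occluder], dtype=float)
    occ_rmax = max(a.radius for a in occluder) + probe
    tree = cKDTree(occ_coords)
    affected = [
        i for i, a in enumerate(mhc)
        if tree.query_ball_point(np.array(a.xyz),
                                 a.radius + probe + occ_rmax,
                                 return_length=True) > 0
    ]
    if not affected:
        return []
    both = compute_sasa(mhc + occluder, probe, n_points,
                        subset=affected).areas
    return [mhc[i] for i in affected if alone[i] - both[i] > epsilon]


def _mhc_atoms(sc: StandardComplex, lenient: bool) -> list[TypedAtom]:
    return (typed_atoms(sc.alpha, "A", lenient=lenient)
            + typed_atoms(sc.beta, "B", lenient=lenient))


def groove_atoms(sc: StandardComplex, epsilon: float = DEFAULT_EPSILON,
                 probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
                 *, lenient: bool = False,
                 _alone: np.ndarray | None = None) -> Pocket:
    """The whole binding groove: MHC atoms occluded by the bound peptide."""
    if not sc.peptide:
        raise InputError("complex has no peptide; groove is undefined")
    mhc = _mhc_atoms(sc, lenient)
    pep = typed_atoms(sc.peptide, "C", lenient=lenient)
    atoms = _occluded(mhc, pep, epsilon, probe, n_points, alone=_alone)
    if len(atoms) < 3:
        raise ExtractionError(
            f"{sc.source}: peptide occludes {len(atoms)} MHC atoms (<3); "
            "no scorable groove")
    return Pocket("whole", atoms, sc.source)


def subpocket_atoms(sc: StandardComplex, which: str,
                    epsilon: float = DEFAULT_EPSILON,
                    probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS,
                    *, lenient: bool = False,
                    _alone: np.ndarray | None = None) -> Pocket:
    """One anchor sub-pocket: MHC atoms occluded by the single peptide
    residue at the mapped harmonized position (its full side chain and
    backbone, as crystallized)."""
    if which not in SUBPOCKET_POSITIONS:
        raise InputError(f"unknown sub-pocket {which!r}; expected one of "
                         f"{sorted(SUBPOCKET_POSITIONS)}")
    pos = SUBPOCKET_POSITIONS[which]
    residue = next((r for r in sc.peptide if r.seq == pos), None)
    if residue is None:
        raise MissingResidueError(
            f"{sc.source}: peptide position {pos} ({which}) absent")
    mhc = _mhc_atoms(sc, lenient)
    occluder = typed_atoms([residue], "C", lenient=lenient)
    atoms = _occluded(mhc, occluder, epsilon, probe, n_points, alone=_alone)
    if len(atoms) < 3:
        raise ExtractionError(
            f"{sc.source}: residue at {pos} occludes {len(atoms)} MHC atoms "
            f"(<3); no scorable {which} sub-pocket")
    return Pocket(which, atoms, sc.source)


def extract_pockets(sc: StandardComplex, kinds: tuple[str, ...] = POCKET_KINDS,
                    epsilon: float = DEFAULT_EPSILON,
                    probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS,
                    *, lenient: bool = False) -> dict[str, Pocket]:
    """Extract several pockets; sub-pockets that fail extraction are omitted
    (the whole groove is mandatory and re-raises). The peptide-free SASA of
    the MHC atoms is computed once and shared across all pockets."""
    alone = compute_sasa(_mhc_atoms(sc, lenient), probe, n_points).areas
    out: dict[str, Pocket] = {}
    for kind in kinds:
        if kind == "whole":
            out[kind] = groove_atoms(sc, epsilon, probe, n_points,
                                     lenient=lenient, _alone=alone)
        else:
            try:
                out[kind] = subpocket_atoms(sc, kind, epsilon, probe, n_points,
                                            lenient=lenient, _alone=alone)
            except (ExtractionError, MissingResidueError):
                continue
    return out


# ---------------------------------------------------------------------------
# pocket file I/O (annotated PDB + sidecar table)

def write_pocket(pocket: Pocket, pdb_path, table_path=None) -> None:
    """Write a pocket as an annotated PDB (occupancy flags membership) plus a
    tab-separated sidecar with chain, residue, atom and group type."""
    from pathlib import Path

    pdb_path = Path(pdb_path)
    lines = []
    for i, a in enumerate(pocket.atoms, start=1):
        lines.append(
            "ATOM  %5d %-4s %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
            % (i, a.atom_name if len(a.atom_name) >= 4 else " " + a.atom_name,
               a.res_name, a.chain, a.res_seq, a.x, a.y, a.z, 1.0, 0.0,
               a.atom_name[0]))
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")
    if table_path is not None:
        rows = ["chain\tres_seq\tres_name\tatom\tgroup\tx\ty\tz"]
        rows += [f"{a.chain}\t{a.res_seq}\t{a.res_name}\t{a.atom_name}\t"
                 f"{a.group}\t{a.x:.3f}\t{a.y:.3f}\t{a.z:.3f}"
                 for a in pocket.atoms]
        Path(table_path).write_text("\n".join(rows) + "\n")


def read_pocket(table_path, kind: str = "whole", source: str = "") -> Pocket:
    """Read a pocket back from its sidecar table."""
    from pathlib import Path

    from .atom_typing import group_radius

    atoms = []
    for line in Path(table_path).read_text().splitlines()[1:]:
        chain, seq, res, atom, group, x, y, z = line.split("\t")
        atoms.append(TypedAtom(float(x), float(y), float(z), group,
                               group_radius(group), chain=chain, res_name=res,
                               res_seq=int(seq), atom_name=atom))
    return Pocket(kind, atoms, source or str(table_path))
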