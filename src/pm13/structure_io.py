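"""Reading, identifying and standardizing MHC class II–peptide complexes.

An MHC class II binding domain is formed by the α1 domain of the alpha
chain and the β1 domain of the beta chain, with a short peptide lying in
the groove between them. To compare grooves across crystal structures the
complexes are brought into a single convention: chains relabelled A (α1),
B (β1), C (peptide); α1 residues renumbered to reference positions 5–78 and
β1 residues to 5–91; peptide residues renumbered to the 13 harmonized
positions 308–320 (P1=308, P4=311, P6=313, P7=314, P9=316); and the whole
complex rigid-body superposed onto the reference frame. Peptide residues
beyond the 13 reference positions are trimmed.

The reference frame ships with the package as a small plain-text asset.
It is a *synthetic* reference complex (see :mod:`pm13.fixtures`), not an
experimentally determined structure: renumbering and superposition only
require a fixed, self-consistent anchor, which the asset provides.

PDB files are read and written through gemmi; only heavy atoms of amino
acid residues are retained (hydrogens, waters and other heteroatoms are
dropped; for alternate locations the highest-occupancy conformer wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align
from Bio.Data.PDBData import protein_letters_3to1

from .errors import (
    ContractError,
    DetectionError,
    FormatError,
    InputError,
    StandardizationError,
)

ALPHA_RANGE = (5, 78)    # α1 domain reference positions retained
BETA_RANGE = (5, 91)     # β1 domain reference positions retained
PEPTIDE_RANGE = (308, 320)  # harmonized peptide positions (13 residues)

#: Harmonized peptide position of each anchor sub-pocket.
SUBPOCKET_POSITIONS = {"P1": 308, "P4": 311, "P6": 313, "P7": 314, "P9": 316}


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    name: str
    seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(protein_letters_3to1.get(r.name, "X") for r in self.residues)

    def centroid(self) -> np.ndarray:
        pts = [a.xyz for r in self.residues for a in r.atoms]
        return np.mean(pts, axis=0)


@dataclass
class RawStructure:
    entry_id: str
    chains: list[Chain]

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.id == cid:
                return c
        raise InputError(f"chain {cid!r} not present in {self.entry_id}")


@dataclass
class ComplexSpec:
    """Which chains form one α/β/peptide complex.

    ``peptide_range`` covers engineered constructs where the peptide is part
    of an MHC chain: a (chain id, first seq, last seq) author-numbering
    range; ``peptide_chain`` is then None.
    """

    alpha_chain: str
    beta_chain: str
    peptide_chain: str | None = None
    peptide_range: tuple[str, int, int] | None = None

    def validate(self, raw: RawStructure) -> None:
        if (self.peptide_chain is None) == (self.peptide_range is None):
            raise InputError("exactly one of peptide_chain / peptide_range required")
        raw.chain(self.alpha_chain)
        raw.chain(self.beta_chain)
        if self.alpha_chain == self.beta_chain:
            raise InputError("alpha and beta selections must be disjoint")
        if self.peptide_chain is not None:
            raw.chain(self.peptide_chain)
            if self.peptide_chain in (self.alpha_chain, self.beta_chain):
                raise InputError("peptide selection overlaps an MHC chain")
        else:
            raw.chain(self.peptide_range[0])


@dataclass
class ReferenceFrame:
    """The packaged reference: domain sequences, canonical numbering and Cα
    coordinates (synthetic; see module docstring)."""

    alpha_seq: str
    beta_seq: str
    peptide_seq: str
    alpha_ca: dict[int, np.ndarray]
    beta_ca: dict[int, np.ndarray]
    peptide_ca: dict[int, np.ndarray]


@dataclass
class StandardComplex:
    """A complex in the common frame: chains A/B/C, reference numbering."""

    alpha: list[Residue]
    beta: list[Residue]
    peptide: list[Residue]
    rotation: np.ndarray
    translation: np.ndarray
    source: str

    def chain(self, cid: str) -> list[Residue]:
        return {"A": self.alpha, "B": self.beta, "C": self.peptide}[cid]

    def validate(self) -> None:
        for residues, (lo, hi), label in (
            (self.alpha, ALPHA_RANGE, "A"),
            (self.beta, BETA_RANGE, "B"),
            (self.peptide, PEPTIDE_RANGE, "C"),
        ):
            for r in residues:
                if not lo <= r.seq <= hi:
                    raise ContractError(
                        f"chain {label} residue {r.seq} outside [{lo}, {hi}]")
        if len(self.peptide) > 13:
            raise ContractError("peptide longer than 13 residues")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ContractError("transform is not a proper rotation")


# ---------------------------------------------------------------------------
# parsing

_WATERS = {"HOH", "DOD", "WAT"}


def _is_amino(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc order."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            by_name[a.name] = a
    # preserve file order of first appearance
    seen, out = set(), []
    for a in atoms:
        if a.name not in seen:
            seen.add(a.name)
            out.append(by_name[a.name])
    return out


def _neg_ord(altloc: str) -> float:
    # earlier altloc letters win ties -> larger key
    return -ord(altloc) if altloc else 1.0


def parse_structure(path: str | Path) -> RawStructure:
    """Parse a PDB file into a :class:`RawStructure`.

    Hydrogens, waters and non-amino-acid heteroatoms are excluded; for
    altloc groups the highest-occupancy conformer is kept.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    chains: list[Chain] = []
    for model in st:
        for ch in model:
            residues: list[Residue] = []
            for res in ch:
                if res.name in _WATERS or not _is_amino(res.name):
                    continue
                atoms = [
                    Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z,
                         a.occ, a.b_iso, a.altloc)
                    for a in res
                    if not a.is_hydrogen()
                ]
                atoms = _dedupe_altlocs(atoms)
                if atoms:
                    residues.append(Residue(res.name, res.seqid.num,
                                            res.seqid.icode.strip(), atoms))
            if residues:
                chains.append(Chain(ch.name, residues))
        break  # first model only
    if not chains:
        raise InputError(f"{path}: no amino-acid ATOM records")
    if len({c.id for c in chains}) != len(chains):
        merged: dict[str, Chain] = {}
        for c in chains:
            merged.setdefault(c.id, Chain(c.id)).residues.extend(c.residues)
        chains = list(merged.values())
    return RawStructure(path.stem.upper(), chains)


# ---------------------------------------------------------------------------
# reference frame

def _parse_frame_text(text: str) -> ReferenceFrame:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            sections[current] = []
        else:
            sections[current].append(line)

    def seq(key: str) -> str:
        return "".join(sections[key])

    def coords(key: str) -> dict[int, np.ndarray]:
        out = {}
        for line in sections[key]:
            pos, x, y, z = line.split()
            out[int(pos)] = np.array([float(x), float(y), float(z)])
        return out

    return ReferenceFrame(seq("ALPHA_SEQ"), seq("BETA_SEQ"), seq("PEPTIDE_SEQ"),
                          coords("ALPHA_CA"), coords("BETA_CA"), coords("PEPTIDE_CA"))


_REFERENCE: ReferenceFrame | None = None


def load_reference() -> ReferenceFrame:
    """Load the packaged (synthetic) reference frame."""
    global _REFERENCE
    if _REFERENCE is None:
        text = resources.files("pm13.data").joinpath(
            "reference_frame_synthetic.txt").read_text()
        _REFERENCE = _parse_frame_text(text)
    return _REFERENCE


# ---------------------------------------------------------------------------
# sequence alignment

@dataclass
class DomainAlignment:
    """Mapping from query residue index (0-based) to reference position."""

    mapping: dict[int, int]
    score: float
    identity: float
    low_identity: bool


def align_domain_sequence(query: str, ref: str, *, ref_start: int = 0,
                          match: float = 1.0, mismatch: float = 0.0,
                          gap: float = -1.0) -> DomainAlignment:
    """Globally align a query domain sequence to a reference profile.

    Returns a strictly increasing mapping query index → reference position
    (``ref_start`` + reference index). Identity below 30% only flags the
    result; MHC class II binding domains are homologous by construction, so
    alignment proceeds regardless.
    """
    if len(query) < 30:
        raise InputError(f"query too short to be a binding domain ({len(query)} < 30)")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(query, ref)[0]
    mapping: dict[int, int] = {}
    n_ident = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for off in range(qe - qs):
            qi, ri = qs + off, rs + off
            mapping[qi] = ref_start + ri
            if query[qi] == ref[ri]:
                n_ident += 1
    identity = n_ident / max(len(query), len(ref))
    return DomainAlignment(mapping, float(aln.score), identity, identity < 0.30)


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, via SVD).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile onto target;
    R is a proper rotation (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("coordinate lists must be equal-length (n,3) arrays")
    if len(mobile) < 3:
        raise InputError("need at least 3 points for superposition")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# complex identification

def identify_complexes(raw: RawStructure, spec: ComplexSpec | None = None,
                       ref: ReferenceFrame | None = None) -> list[ComplexSpec]:
    """Find (α, β, peptide) chain triples in a structure.

    With an explicit spec it is validated and returned. Otherwise chains of
    70–120 residues are scored against the reference α1/β1 profiles, the
    best-scoring pair becomes (A, B) and the nearest remaining 9–25 residue
    chain the peptide; several triples may be found (multi-copy entries).
    """
    if spec is not None:
        spec.validate(raw)
        return [spec]
    if len(raw.chains) < 2:
        raise DetectionError(
            f"{raw.entry_id}: fewer than two chains; pass an explicit ComplexSpec")
    ref = ref or load_reference()
    domain_like = [c for c in raw.chains if 70 <= len(c) <= 120]
    peptide_like = [c for c in raw.chains if 9 <= len(c) <= 25]
    scores: dict[str, tuple[float, float]] = {}
    for c in domain_like:
        a = align_domain_sequence(c.sequence(), ref.alpha_seq).score
        b = align_domain_sequence(c.sequence(), ref.beta_seq).score
        scores[c.id] = (a, b)

    specs: list[ComplexSpec] = []
    remaining = list(raw.chains)
    while True:
        doms = [c for c in remaining if c.id in scores]
        peps = [c for c in remaining if c in peptide_like]
        if len(doms) < 2 or not peps:
            break
        alpha = max(doms, key=lambda c: scores[c.id][0])
        beta = max((c for c in doms if c.id != alpha.id),
                   key=lambda c: scores[c.id][1])
        center = (alpha.centroid() + beta.centroid()) / 2
        pep = min(peps, key=lambda c: float(np.linalg.norm(c.centroid() - center)))
        specs.append(ComplexSpec(alpha.id, beta.id, pep.id))
        remaining = [c for c in remaining if c.id not in (alpha.id, beta.id, pep.id)]
    if not specs:
        raise DetectionError(
            f"{raw.entry_id}: no α/β/peptide triple found; pass an explicit "
            "ComplexSpec naming the chains")
    return specs


# ---------------------------------------------------------------------------
# standardization

def _transform_residues(residues: list[Residue], rot: np.ndarray,
                        trans: np.ndarray) -> list[Residue]:
    out = []
    for r in residues:
        atoms = []
        for a in r.atoms:
            x, y, z = rot @ a.xyz + trans
            atoms.append(Atom(a.name, a.element, float(x), float(y), float(z),
                              a.occupancy, a.bfactor))
        out.append(Residue(r.name, r.seq, r.icode, atoms))
    return out


def _map_domain(chain: Chain, ref_seq: str, ref_start: int, label: str
                ) -> dict[int, int]:
    aln = align_domain_sequence(chain.sequence(), ref_seq, ref_start=ref_start)
    if len(aln.mapping) < 0.5 * len(ref_seq):
        raise StandardizationError(
            f"chain {chain.id}: only {len(aln.mapping)}/{len(ref_seq)} "
            f"{label} positions mapped (<50%)")
    return aln.mapping


def _peptide_residues(raw: RawStructure, spec: ComplexSpec) -> list[Residue]:
    if spec.peptide_chain is not None:
        return raw.chain(spec.peptide_chain).residues
    cid, lo, hi = spec.peptide_range
    return [r for r in raw.chain(cid).residues if lo <= r.seq <= hi]


def _assign_peptide(residues: list[Residue], ref: ReferenceFrame,
                    cutoff: float) -> list[tuple[int, int]]:
    """Maximum-cardinality order-consistent assignment of peptide residues
    to reference peptide positions (nearest-Cα, each position used once).

    Returns (residue index, reference position) pairs. Among equal-size
    assignments the one with the smallest total Cα distance wins.
    """
    positions = sorted(ref.peptide_ca)
    dist = {}
    for j, res in enumerate(residues):
        ca = res.atom("CA")
        if ca is None:
            continue
        for p in positions:
            d = float(np.linalg.norm(ca.xyz - ref.peptide_ca[p]))
            if d <= cutoff:
                dist[(j, p)] = d

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(j: int, k: int) -> tuple[int, float, tuple]:
        # best (count, -total_dist...) assigning residues j.. to positions >= positions[k]
        if j >= len(residues) or k >= len(positions):
            return (0, 0.0, ())
        skip = best(j + 1, k)
        options = [skip]
        for ki in range(k, len(positions)):
            p = positions[ki]
            d = dist.get((j, p))
            if d is None:
                continue
            cnt, total, pairs = best(j + 1, ki + 1)
            options.append((cnt + 1, total + d, ((j, p),) + pairs))
        return max(options, key=lambda o: (o[0], -o[1]))

    return list(best(0, 0)[2])


def standardize_complex(raw: RawStructure, spec: ComplexSpec,
                        ref: ReferenceFrame | None = None,
                        peptide_cutoff: float = 8.0) -> StandardComplex:
    """Renumber, relabel, trim and superpose one complex onto the reference.

    α1 and β1 are renumbered via global sequence alignment to the reference
    profiles and trimmed to positions 5–78 / 5–91; the complex is superposed
    over all mapped Cα pairs of both domains jointly; peptide residues are
    assigned to the 13 reference positions by nearest reference Cα after
    superposition (injective, sequence-order consistent) and the rest
    removed.
    """
    ref = ref or load_reference()
    spec.validate(raw)
    alpha_chain = raw.chain(spec.alpha_chain)
    beta_chain = raw.chain(spec.beta_chain)
    amap = _map_domain(alpha_chain, ref.alpha_seq, ALPHA_RANGE[0], "α1")
    bmap = _map_domain(beta_chain, ref.beta_seq, BETA_RANGE[0], "β1")

    mobile, target = [], []
    for chain, mapping, ref_ca in ((alpha_chain, amap, ref.alpha_ca),
                                   (beta_chain, bmap, ref.beta_ca)):
        for qi, pos in mapping.items():
            ca = chain.residues[qi].atom("CA")
            if ca is not None and pos in ref_ca:
                mobile.append(ca.xyz)
                target.append(ref_ca[pos])
    rot, trans, _ = kabsch_superpose(np.array(mobile), np.array(target))

    def build_domain(chain: Chain, mapping: dict[int, int],
                     lo: int, hi: int) -> list[Residue]:
        out = []
        for qi, pos in sorted(mapping.items(), key=lambda kv: kv[1]):
            if lo <= pos <= hi:
                src = chain.residues[qi]
                res = _transform_residues([src], rot, trans)[0]
                res.seq, res.icode = pos, ""
                out.append(res)
        return out

    alpha = build_domain(alpha_chain, amap, *ALPHA_RANGE)
    beta = build_domain(beta_chain, bmap, *BETA_RANGE)

    pep_src = _transform_residues(_peptide_residues(raw, spec), rot, trans)
    pairs = _assign_peptide(pep_src, ref, peptide_cutoff)
    if not pairs:
        raise StandardizationError(
            f"{raw.entry_id}: no peptide residue lies near the reference "
            "peptide after superposition")
    peptide = []
    for j, pos in pairs:
        res = pep_src[j]
        res.seq, res.icode = pos, ""
        peptide.append(res)

    orig = f"{spec.alpha_chain}{spec.beta_chain}{spec.peptide_chain or spec.peptide_range[0]}"
    sc = StandardComplex(alpha, beta, peptide, rot, trans,
                         source=f"{raw.entry_id}-{orig}")
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# writing

def write_standard_pdb(sc: StandardComplex, path: str | Path) -> Path:
    """Write a standardized complex as a PDB file with chains A/B/C."""
    sc.validate()
    if not sc.peptide:
        raise ContractError("refusing to write a complex with an empty peptide chain")
    st = gemmi.Structure()
    st.name = sc.source
    model = gemmi.Model("1")
    for cid in "ABC":
        chain = gemmi.Chain(cid)
        for r in sc.chain(cid):
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seq, " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                atom.occ = a.occupancy
                atom.b_iso = a.bfactor
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
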