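"""Synthetic test structures: pockets and miniature MHC-like complexes.

Real MHC class II crystal structures cannot be assumed to be on disk, so
every pipeline stage is exercised on generated inputs: bare typed point
clouds (for the descriptor and scoring layers) and small but valid PDB
files containing a two-chain "groove" with a peptide threaded through it
(for parsing, standardization and pocket extraction). Geometry is
deliberately schematic — two serpentine backbone rails flanking the
peptide — not physically realistic protein structure; each residue carries
the five heavy atoms N, CA, C, O, CB (no CB for glycine).

The packaged reference frame (``data/reference_frame_synthetic.txt``) is
the canonical complex produced by this module with fixed synthetic
sequences, frozen to a text asset. It is synthetic: it anchors numbering
and superposition, nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .accessibility import Pocket
from .atom_typing import GROUP_TYPES, TypedAtom, group_radius
from .errors import FixtureError, InputError
from .structure_io import ALPHA_RANGE, BETA_RANGE, PEPTIDE_RANGE

# Fixed synthetic domain sequences (all 20 residue types occur in each
# domain, so the full typing table is exercised).
REF_ALPHA_SEQ = "DSCYTRDISTASDQEGICAFPVCNWQFAPIIIDQWKQYRLGTCVEIEYCEEEQCMPPLVKSHFEIEATTTPYSN"
REF_BETA_SEQ = ("CVYAVVERLMWRFKAGAAHGRKTKYDMYNNHELTAFLCMVTSVPDCAEHWNQMQIRYIAS"
                "SHWTDERTPVGKHIFIWTLEQFNMMCC")
REF_PEPTIDE_SEQ = "CWVIPSNPEDVWH"

_CA_STEP = 3.8       # rail Cα spacing, Å
_PEP_STEP = 3.5      # peptide Cα spacing, Å


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture (pocket or complex)."""

    seed: int = 0
    n_atoms: int = 40
    palette: tuple[str, ...] = GROUP_TYPES
    template: str = "random-cloud"  # cup | two-helix-groove | random-cloud
    peptide_len: int = 13
    n_copies: int = 1
    peptide_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter: float = 0.0  # Å of per-atom coordinate noise


# ---------------------------------------------------------------------------
# bare pockets

def make_pocket(spec: FixtureSpec) -> Pocket:
    """A random typed point cloud with a minimum inter-atom spacing of
    1.5 Å (rejection sampling), deterministic given the seed."""
    if spec.n_atoms < 3:
        raise InputError("a scorable pocket needs at least 3 atoms")
    rng = np.random.default_rng(spec.seed)
    box = 1.8 * spec.n_atoms ** (1 / 3) * 1.5  # loose packing
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < spec.n_atoms:
        attempts += 1
        if attempts > 200 * spec.n_atoms:
            raise FixtureError("could not pack atoms at 1.5 Å spacing")
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - c) >= 1.5 for c in coords):
            coords.append(cand)
    groups = [spec.palette[i] for i in rng.integers(0, len(spec.palette),
                                                    spec.n_atoms)]
    atoms = [TypedAtom(float(c[0]), float(c[1]), float(c[2]), g,
                       group_radius(g), chain="A", res_seq=i + 1,
                       atom_name="X")
             for i, (c, g) in enumerate(zip(coords, groups))]
    return Pocket("whole", atoms, f"fixture-seed{spec.seed}")


def make_cup(n_wall: int = 6, radius: float = 3.2) -> tuple[list[TypedAtom], TypedAtom]:
    """A ring of wall atoms plus one probe atom resting in the cup —
    the minimal occlusion geometry used by accessibility oracles."""
    wall = []
    for i in range(n_wall):
        ang = 2 * math.pi * i / n_wall
        wall.append(TypedAtom(radius * math.cos(ang), radius * math.sin(ang),
                              0.0, "C4H2", group_radius("C4H2"),
                              chain="A", res_seq=i + 1, atom_name="C"))
    probe = TypedAtom(0.0, 0.0, 1.8, "C4H3", group_radius("C4H3"),
                      chain="C", res_seq=1, atom_name="C")
    return wall, probe


# ---------------------------------------------------------------------------
# groove complexes

def _serpentine(n: int, x_center: float, y_in: float, y_out: float,
                phase: float) -> list[np.ndarray]:
    row = (n + 1) // 2
    x0 = x_center - _CA_STEP * (row - 1) / 2
    pts = []
    for i in range(n):
        if i < row:
            x, y = x0 + _CA_STEP * i, y_in
        else:
            x, y = x0 + _CA_STEP * (2 * row - 1 - i), y_out
        z = 0.8 * math.sin(0.9 * i + phase)
        pts.append(np.array([x, y, z]))
    return pts


def _residue_atoms(ca: np.ndarray, cb_dir: np.ndarray, resname: str
                   ) -> list[tuple[str, str, np.ndarray]]:
    atoms = [("N", "N", ca + np.array([-1.20, 0.55, 0.45])),
             ("CA", "C", ca),
             ("C", "C", ca + np.array([1.26, 0.55, 0.40]))]
    atoms.append(("O", "O", atoms[-1][2] + np.array([0.15, 1.22, 0.05])))
    if resname != "GLY":
        atoms.append(("CB", "C", ca + cb_dir))
    return atoms


def _chain_residues(sequence: str, ca_path: list[np.ndarray],
                    cb_dir: np.ndarray, rng: np.random.Generator,
                    jitter: float) -> list[tuple[str, list]]:
    residues = []
    for one, ca in zip(sequence, ca_path):
        resname = protein_letters_1to3[one].upper()
        atoms = []
        for name, element, pos in _residue_atoms(ca, cb_dir, resname):
            if jitter:
                pos = pos + rng.normal(scale=jitter, size=3)
            atoms.append((name, element, pos))
        residues.append((resname, atoms))
    return residues


def _build_complex_chains(spec: FixtureSpec) -> dict[str, list]:
    """Chain id → residue list for one synthetic groove complex."""
    rng = np.random.default_rng(spec.seed)
    pep_len = spec.peptide_len
    if pep_len < 1:
        raise InputError("peptide must have at least one residue")
    center = _PEP_STEP * 12 / 2  # midpoint of the 13 reference positions

    alpha = _chain_residues(
        REF_ALPHA_SEQ, _serpentine(len(REF_ALPHA_SEQ), center, 4.3, 8.1, 0.0),
        np.array([0.30, -1.25, 0.55]), rng, spec.jitter)
    beta = _chain_residues(
        REF_BETA_SEQ, _serpentine(len(REF_BETA_SEQ), center, -4.3, -8.1, 1.3),
        np.array([0.30, 1.25, 0.55]), rng, spec.jitter)

    lead = (pep_len - 13) // 2 if pep_len > 13 else 0
    pep_seq = "".join(REF_PEPTIDE_SEQ[(i - lead) % 13] for i in range(pep_len))
    shift = np.asarray(spec.peptide_shift, dtype=float)
    pep_path = [np.array([_PEP_STEP * (i - lead),
                          0.0,
                          1.6 + 0.15 * math.sin(1.1 * i)]) + shift
                for i in range(pep_len)]
    peptide = _chain_residues(pep_seq, pep_path,
                              np.array([0.30, 0.45, -1.30]), rng, spec.jitter)
    return {"A": alpha, "B": beta, "C": peptide}


def make_complex_pdb(spec: FixtureSpec, path: str | Path) -> Path:
    """Write a synthetic groove complex as a PDB file.

    One copy uses chains A/B/C; a second copy (``n_copies=2``) adds D/E/F
    translated far away, emulating two molecules per asymmetric unit.
    """
    if spec.n_copies not in (1, 2):
        raise InputError("n_copies must be 1 or 2")
    st = gemmi.Structure()
    st.name = f"fixture-seed{spec.seed}"
    model = gemmi.Model("1")
    copies = [("ABC", np.zeros(3))]
    if spec.n_copies == 2:
        copies.append(("DEF", np.array([0.0, 0.0, 120.0])))
    chains = _build_complex_chains(spec)
    for ids, offset in copies:
        for cid, src in zip(ids, "ABC"):
            chain = gemmi.Chain(cid)
            for seq, (resname, atoms) in enumerate(chains[src], start=1):
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(seq, " ")
                for name, element, pos in atoms:
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.element = gemmi.Element(element)
                    p = pos + offset
                    atom.pos = gemmi.Position(p[0], p[1], p[2])
                    atom.occ = 1.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# the packaged reference frame

def reference_frame_text() -> str:
    """The content of the synthetic reference-frame asset, regenerated from
    the canonical fixture geometry (seed 0, no jitter)."""
    chains = _build_complex_chains(FixtureSpec(seed=0))
    lines = ["# Synthetic reference frame for complex standardization.",
             "# Generated by pm13.fixtures.reference_frame_text(); regenerate with",
             "#   python -c 'import pm13.fixtures as f; print(f.reference_frame_text())'",
             "# Sections: sequences and CA coordinates (position x y z, Angstrom)."]

    def add_seq(tag: str, seq: str) -> None:
        lines.append(f">{tag}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i:i + 60])

    def add_ca(tag: str, residues: list, start: int) -> None:
        lines.append(f">{tag}")
        for pos, (_, atoms) in enumerate(residues, start=start):
            ca = next(p for name, _, p in atoms if name == "CA")
            lines.append(f"{pos} {ca[0]:.6f} {ca[1]:.6f} {ca[2]:.6f}")

    add_seq("ALPHA_SEQ", REF_ALPHA_SEQ)
    add_seq("BETA_SEQ", REF_BETA_SEQ)
    add_seq("PEPTIDE_SEQ", REF_PEPTIDE_SEQ)
    add_ca("ALPHA_CA", chains["A"], ALPHA_RANGE[0])
    add_ca("BETA_CA", chains["B"], BETA_RANGE[0])
    add_ca("PEPTIDE_CA", chains["C"], PEPTIDE_RANGE[0])
    return "\n".join(lines) + "\n"


def make_corpus(directory: str | Path, n_complexes: int = 3,
                base_seed: int = 0) -> list[Path]:
    """Write a small corpus of jittered groove complexes (the test corpus
    behind pipeline and CLI checks)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(n_complexes):
        spec = FixtureSpec(seed=base_seed + k, jitter=0.0 if k == 0 else 0.25)
        paths.append(make_complex_pdb(spec, directory / f"fix{k:02d}.pdb"))
    return paths
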