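"""ProtOr atomic group typing.

Each heavy atom of a protein, together with its covalently attached
hydrogens, is treated as a single united group. Groups are labelled by the
heavy-atom element, the total covalent connectivity and the attached
hydrogen count — e.g. ``C4H3`` is a methyl carbon, ``O1H0`` a carbonyl
oxygen. Over the 20 standard amino acids exactly 13 such group types occur:

    C3H0 C3H1 C4H1 C4H2 C4H3 N3H0 N3H1 N3H2 N4H3 O1H0 O2H1 S2H0 S2H1

Each group carries a ProtOr united-group radius (Å), used by the
accessibility module in place of bare van der Waals radii. The
(residue, atom) → group mapping and the radii ship as a plain-text,
user-auditable asset (``data/protor_typing.tsv``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

from .errors import TypingError

#: The closed set of 13 ProtOr group labels, in canonical order.
GROUP_TYPES: tuple[str, ...] = (
    "C3H0", "C3H1", "C4H1", "C4H2", "C4H3",
    "N3H0", "N3H1", "N3H2", "N4H3",
    "O1H0", "O2H1", "S2H0", "S2H1",
)

GROUP_INDEX: dict[str, int] = {g: i for i, g in enumerate(GROUP_TYPES)}

#: Aliases for common nonstandard residues (selenomethionine etc.).
RESIDUE_ALIASES: dict[str, str] = {"MSE": "MET"}
#: Atom-name aliases applied together with residue aliases.
_ATOM_ALIASES: dict[tuple[str, str], str] = {("MSE", "SE"): "SD"}


@dataclass(frozen=True)
class TypedAtom:
    """A heavy atom with coordinates, ProtOr group type and provenance."""

    x: float
    y: float
    z: float
    group: str
    radius: float
    chain: str = "?"
    res_name: str = "UNK"
    res_seq: int = 0
    atom_name: str = "?"

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@functools.lru_cache(maxsize=1)
def load_typing_table() -> tuple[dict[tuple[str, str], str], dict[str, float]]:
    """Load the (residue, atom) → group mapping and the group → radius table."""
    assignments: dict[tuple[str, str], str] = {}
    radii: dict[str, float] = {}
    text = resources.files("pm13.data").joinpath("protor_typing.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        res, atom, group, radius = line.split("\t")
        assignments[(res, atom)] = group
        radii[group] = float(radius)
    if set(radii) != set(GROUP_TYPES):  # pragma: no cover - asset integrity
        raise AssertionError("typing asset does not cover the 13 group types")
    return assignments, radii


def assign_group_type(residue_name: str, atom_name: str, *, allow_aliases: bool = True) -> str:
    """Return the ProtOr group label for a heavy atom.

    Protonation-dependent atoms (HIS ring nitrogens, chain termini) use the
    table's single fixed assignment so typing is deterministic. Unknown
    pairs raise :class:`TypingError` carrying the offending names.
    """
    assignments, _ = load_typing_table()
    res, atom = residue_name.upper(), atom_name.upper()
    if allow_aliases:
        atom = _ATOM_ALIASES.get((res, atom), atom)
        res = RESIDUE_ALIASES.get(res, res)
    try:
        return assignments[(res, atom)]
    except KeyError:
        raise TypingError(residue_name, atom_name) from None


def group_radius(group: str) -> float:
    """ProtOr radius (Å) of a group type; total on the 13-label enum."""
    _, radii = load_typing_table()
    try:
        return radii[group]
    except KeyError:
        raise TypingError("<group>", group) from None


def type_atom(residue_name: str, atom_name: str, x: float, y: float, z: float,
              *, chain: str = "?", res_seq: int = 0) -> TypedAtom:
    """Convenience constructor: assign group + radius and build a TypedAtom."""
    group = assign_group_type(residue_name, atom_name)
    return TypedAtom(x, y, z, group, group_radius(group),
                     chain=chain, res_name=residue_name.upper(),
                     res_seq=res_seq, atom_name=atom_name.upper())
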