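"""Exception hierarchy.

All package errors derive from :class:`Pm13Error` so callers can catch one
base class; the subclasses mirror the pipeline stages (parsing, complex
detection, standardization, atom typing, pocket extraction, scoring).
"""


class Pm13Error(Exception):
    """Base class for all pm13 errors."""


class FormatError(Pm13Error):
    """A file could not be parsed as PDB; the message names the offence."""


class InputError(Pm13Error):
    """An argument violates an operation's precondition."""


class ContractError(Pm13Error):
    """An internal data contract was violated (e.g. unsorted distance list)."""


class DetectionError(Pm13Error):
    """No alpha/beta/peptide triple could be identified in a structure."""


class StandardizationError(Pm13Error):
    """A complex could not be mapped onto the reference frame."""


class TypingError(Pm13Error):
    """A (residue, atom) pair has no ProtOr group assignment."""

    def __init__(self, residue_name: str, atom_name: str):
        self.residue_name = residue_name
        self.atom_name = atom_name
        super().__init__(f"no atomic group type for ({residue_name}, {atom_name})")


class ExtractionError(Pm13Error):
    """Pocket extraction produced too few atoms to be scorable."""


class MissingResidueError(Pm13Error):
    """A required peptide anchor position is absent from the complex."""


class DescriptorError(Pm13Error):
    """A pocket is unsuitable for descriptor construction or comparison."""


class FixtureError(Pm13Error):
    """Synthetic fixture generation failed (e.g. infeasible packing)."""
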