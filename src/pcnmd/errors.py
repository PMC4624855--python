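"""Exception hierarchy.

Every error raised by the library derives from :class:`PcnmdError`, so CLI
code can map library failures to a single exit status.
"""


class PcnmdError(Exception):
    """Base class for all pcnmd errors."""


class PDBParseError(PcnmdError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(PcnmdError):
    """Input contained no usable records."""


class StructuralMismatchError(PcnmdError):
    """Trajectory models disagree on atom count/ordering."""


class SelectionSyntaxError(PcnmdError):
    """Selection expression violates the grammar."""


class SelectionEmptyError(PcnmdError):
    """An operation required a non-empty selection."""


class SelectionOverlapError(PcnmdError):
    """Two selections that must be disjoint share atoms."""


class MissingAtomError(PcnmdError):
    """A residue lacks an atom required by the operation (e.g. CA)."""


class DegenerateGeometryError(PcnmdError):
    """Too few or collinear points for a rigid superposition."""


class InsufficientFramesError(PcnmdError):
    """Operation needs more trajectory frames than supplied."""


class InsufficientDataError(PcnmdError):
    """Statistical operation needs more observations than supplied."""


class EmptyGraphError(PcnmdError):
    """Graph has no nodes."""


class NoPathError(PcnmdError):
    """Graph has no edges, so no path lengths exist."""


class NoStructureError(PcnmdError):
    """Graph has no edges to cluster."""


class SizeError(PcnmdError):
    """A size parameter is out of range (e.g. k > n_nodes)."""


class ParameterError(PcnmdError):
    """A numeric parameter violates its constraints."""


class ClassificationError(PcnmdError):
    """An atom could not be assigned a solvation class or radius."""


class RadiusError(PcnmdError):
    """No van der Waals radius is known for an element."""


class FormattingOverflowError(PcnmdError):
    """A value does not fit the fixed-width PDB b-factor field."""


class MappingError(PcnmdError):
    """A residue key could not be resolved against the structure."""


class SchemaError(PcnmdError):
    """Tabular input does not match the expected schema."""


class UndefinedContentError(PcnmdError):
    """Cosine content is undefined (all-zero projection)."""
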