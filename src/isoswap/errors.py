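"""Exception hierarchy.

Validation-type errors (bad user input, contract violations detectable up
front) derive from :class:`ValidationError` and map to CLI exit code 2;
everything else derives from :class:`IsoswapError` and maps to exit code 1.
"""


class IsoswapError(Exception):
    """Base class for all package errors."""


class ValidationError(IsoswapError):
    """Bad input or option combination detectable before any computation."""


class PdbFormatError(ValidationError):
    """Unparsable PDB record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class EmptyLigandError(ValidationError):
    """Complex contains no ligand after applying the exclusion set."""


class EmptySiteError(ValidationError):
    """No protein residue within the cutoff of the ligand."""


class UnsupportedElementError(ValidationError):
    """Element outside the supported table (vdW radius / valence unknown)."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"unsupported element: {element!r}")


class DegenerateGeometryError(IsoswapError):
    """Point sets too degenerate (collinear/coincident) for superposition."""


class EmptySubsetError(IsoswapError):
    """Requested surface subset contains no atoms (e.g. no H-bonding atoms)."""


class UndefinedInputError(ValidationError):
    """Operation on an empty point set whose result is undefined."""


class SchemaVersionError(IsoswapError):
    """Pair database written by an incompatible schema version."""


class SelectionRequiredError(ValidationError):
    """A join atom must be selected for a multi-attachment fragment."""


class ReconnectionError(IsoswapError):
    """No valence-feasible partner for a severed attachment."""

    def __init__(self, attachment_index: int, message: str = ""):
        self.attachment_index = attachment_index
        super().__init__(
            message or f"no valence-feasible bond for severed attachment "
            f"at molecule atom {attachment_index}"
        )


class ConnectivityError(IsoswapError):
    """Fragment replacement produced a disconnected molecule."""
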