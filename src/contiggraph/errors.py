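"""Exception hierarchy for contiggraph."""


class ContigGraphError(Exception):
    """Base class for all contiggraph errors."""


class EndLabelError(ContigGraphError):
    """An end label did not parse as '<id>S' or '<id>E'."""


class ReferentialIntegrityError(ContigGraphError):
    """A link references a contig id that is not in the contig table."""


class UndefinedValueError(ContigGraphError):
    """A ratio was requested with a zero or negative denominator."""


class CrsFormatError(ContigGraphError):
    """Malformed CRS (tabbed.txt / tabbedCov.txt) input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AceFormatError(ContigGraphError):
    """Malformed ACE assembly input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SamFormatError(ContigGraphError):
    """Malformed SAM input (e.g. alignment to a contig absent from @SQ)."""


class GraphLookupError(ContigGraphError):
    """A requested contig or link is not present in the graph."""


class GenomeSpecError(ContigGraphError):
    """Inconsistent synthetic-genome specification."""
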