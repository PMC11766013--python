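"""Exception hierarchy. Validation errors all derive from DiagPcrError so the
CLI can map them to exit code 2 uniformly."""


class DiagPcrError(Exception):
    """Base class for all package-raised validation/usage errors."""


class AlignmentShapeError(DiagPcrError):
    """Sequences in an alignment do not share a single length."""


class SequenceContentError(DiagPcrError):
    """Illegal character in a sequence; message names record and column."""


class SpeciesLabelError(DiagPcrError):
    """Missing, empty, or unresolvable species label."""


class SpeciesLookupError(DiagPcrError, KeyError):
    """Requested species not present in the alignment."""


class ParameterError(DiagPcrError):
    """Out-of-domain parameter value (inverted ranges, non-positive [Na+], ...)."""


class CoordinateError(DiagPcrError):
    """Span outside alignment bounds."""


class FitError(DiagPcrError):
    """Not enough usable data to fit a standard curve."""


class PlateFormatError(DiagPcrError):
    """Malformed plate-export table."""
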