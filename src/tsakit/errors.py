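"""Exception hierarchy shared across the pipeline."""


class TsakitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TsakitError):
    """A coordinate or table file could not be parsed."""


class EmptyStructureError(ParseError):
    """A coordinate file yielded zero atoms."""


class MissingAtomError(TsakitError):
    """An atom query matched nothing."""


class AmbiguousAtomError(TsakitError):
    """An atom query matched more than one atom after altloc resolution."""


class LigandIdentificationError(TsakitError):
    """The hetero ligand group could not be identified unambiguously."""


class InsufficientPairsError(TsakitError):
    """Fewer than three shared C-alpha atoms between two structures."""


class DegenerateGeometryError(TsakitError):
    """Point sets are collinear or coincident; no unique rotation exists."""


class DataError(TsakitError):
    """Kinetic input data violate a precondition."""


class FitError(TsakitError):
    """A least-squares fit failed or produced an inadmissible result."""


class NoInhibitionError(FitError):
    """The apparent K_M/V_max does not increase with inhibitor concentration."""


class UnknownElementError(TsakitError):
    """An element symbol is absent from the atomic-weight table."""


class JoinError(TsakitError):
    """Geometry and kinetics inputs do not cover the same ligand set."""


class UndefinedCorrelationError(TsakitError):
    """A correlation is not computable (n < 3 or zero rank variance)."""
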