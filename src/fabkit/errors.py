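"""Exception hierarchy shared across fabkit modules."""


class FabkitError(Exception):
    """Base class for all fabkit errors."""


class FormatError(FabkitError):
    """A structure file could not be parsed."""


class RosterError(FabkitError):
    """Models of a multi-model structure do not share an identical atom roster,
    or a selection names atoms absent from the roster."""


class MissingChainError(FabkitError):
    """A domain map names a chain that is not present in the structure."""


class DomainResolutionError(FabkitError):
    """A required domain resolves too few C-alpha atoms."""


class CoverageError(FabkitError):
    """Too few coreset positions present for frame registration.

    Carries the missing positions in ``missing``.
    """

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class DegenerateGeometryError(FabkitError):
    """Coordinates are collinear/coincident or otherwise rank-deficient."""


class InterfaceSpecError(FabkitError):
    """An interface specification is empty or resolves no atoms."""


class InsufficientDataError(FabkitError):
    """Not enough models/samples for the requested statistic."""
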