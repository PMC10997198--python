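"""Exception hierarchy."""


class PBSQuenchError(Exception):
    """Base class for all package errors."""


class StructureFormatError(PBSQuenchError):
    """Input structure file could not be parsed."""


class NoPigmentsFoundError(PBSQuenchError):
    """No cofactor in the structure matched the extraction rules."""


class MissingAtomsError(PBSQuenchError):
    """A matched cofactor lacks atoms required by the extraction rules."""


class DegenerateGeometryError(PBSQuenchError):
    """Too few or spatially degenerate points for an axis fit."""


class ConfigurationError(PBSQuenchError):
    """Invalid or incomplete run configuration."""


class CoincidentAtomsError(PBSQuenchError):
    """Two transition charges sit at the same coordinates."""


class NonTerminatingStateError(PBSQuenchError):
    """A reachable pigment has no exit channel; a trajectory cannot end."""
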