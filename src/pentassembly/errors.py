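"""Exception hierarchy for pentassembly."""


class PentassemblyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PentassemblyError):
    """A structure file could not be parsed."""


class TopologyError(PentassemblyError):
    """Atoms/residues/chains violate the expected pentapeptide topology."""


class MissingHydrogenError(TopologyError):
    """A required explicit hydrogen is absent (strict hydrogen mode)."""


class ParameterError(PentassemblyError):
    """An operation received an out-of-range or inconsistent parameter."""


class FeasibilityError(PentassemblyError):
    """A stochastic construction could not satisfy its constraints."""


class UsageError(PentassemblyError):
    """An operation was called outside its stated precondition."""


class ConsistencyError(PentassemblyError):
    """Mutually inconsistent inputs (e.g. intra-chain bond flagged inter-aggregate)."""


class PrecisionError(PentassemblyError):
    """Too little data to produce an estimate at useful precision."""
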