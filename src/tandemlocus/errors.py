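"""Exception hierarchy used across the toolkit."""


class TandemLocusError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TandemLocusError):
    """Malformed or empty input file."""


class AlphabetError(TandemLocusError):
    """Sequence contains characters outside the declared alphabet."""


class BoundsError(TandemLocusError):
    """Feature coordinates fall outside the parent sequence."""


class ConfigError(TandemLocusError):
    """Invalid configuration value or unknown dialect/key."""


class StrandError(TandemLocusError):
    """Operation requires a stranded feature but strand is '.'."""


class PlanError(TandemLocusError):
    """Invalid deletion/construction plan (e.g. overlapping deletions)."""


class EstimationError(TandemLocusError):
    """Copy-number estimation cannot proceed (e.g. no vector support)."""


class ModelError(TandemLocusError):
    """Internally inconsistent gene model."""


class EnzymeError(TandemLocusError):
    """Invalid restriction enzyme definition."""


class InputError(TandemLocusError):
    """Invalid operation input (empty sequence, molecule-type mismatch, ...)."""
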