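"""Exception hierarchy shared across the package."""


class TrophnetError(Exception):
    """Base class for all trophnet errors."""


class InvalidInputError(TrophnetError):
    """A value or array violates a precondition (non-finite, negative, wrong shape)."""


class SchemaError(TrophnetError):
    """A tabular input is missing cells/columns or contains duplicates."""


class DegenerateInputError(TrophnetError):
    """The input is structurally valid but too small/empty for the operation."""


class InsufficientReplicationError(TrophnetError):
    """An assay has too few replicates for a hypothesis test."""


class PairingError(TrophnetError):
    """A coculture assay does not match the strain pair it is attributed to."""


class LabelingError(TrophnetError):
    """A strain lacks required metadata (treatment/fraction) labels."""


class ConfigError(TrophnetError):
    """A configuration object is internally inconsistent."""


class AssemblyError(TrophnetError):
    """Pipeline tables cannot be joined because a required piece is missing."""


class DegenerateFitError(TrophnetError):
    """A model fit is requested on data that cannot identify the parameters."""


class InsufficientDataError(TrophnetError):
    """A group comparison has a group with too few observations."""
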