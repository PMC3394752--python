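"""Exception types raised across the package."""


class NocturnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NocturnError):
    """Invalid simulation or analysis configuration (e.g. a transition
    matrix whose rows do not sum to one)."""


class FormatError(NocturnError):
    """A file could not be parsed into the expected structure."""


class TimingError(NocturnError):
    """Recording length or metadata inconsistent with the epoch grid."""


class AlignmentError(NocturnError):
    """Paired inputs (spectra/hypnogram, baseline/recovery) disagree in
    length or zeitgeber alignment."""
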