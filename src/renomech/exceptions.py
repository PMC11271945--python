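"""Exception and warning hierarchy used across the package."""


class RenomechError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RenomechError, ValueError):
    """A caller supplied a physically inadmissible argument."""


class InvalidStateError(RenomechError, ValueError):
    """An internally inconsistent kinematic/damage state was encountered."""


class ConfigurationError(RenomechError, ValueError):
    """Material constants or run configuration are inadmissible."""


class IntegrationError(RenomechError, RuntimeError):
    """A material-point driver failed to advance (e.g. Newton divergence)."""


class FitError(RenomechError, RuntimeError):
    """A least-squares calibration stage failed to converge."""


class ParseError(RenomechError, ValueError):
    """A curve table or parameter file violated its schema."""


class DamageValidityWarning(UserWarning):
    """The damage variable left the range where the softening law is physical."""
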