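"""Exception types raised across the sLTP pipeline."""


class SltpError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(SltpError, ValueError):
    """File is not a readable NIfTI / MetaImage volume."""


class HeaderError(SltpError, ValueError):
    """Volume header is missing required information (e.g. spacing)."""


class ConfigError(SltpError, ValueError):
    """Run configuration failed validation."""


class PhantomSpecError(SltpError, ValueError):
    """Phantom specification is inconsistent (overlapping or out-of-lung regions...)."""


class DegenerateMaskError(SltpError, ValueError):
    """Lung mask has no interior; the Poisson problem is singular."""


class StageError(SltpError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""
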