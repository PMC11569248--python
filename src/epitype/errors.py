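"""Named exception types shared across the package."""


class EpitypeError(Exception):
    """Base class for all package errors."""


class UnknownChromosomeError(EpitypeError):
    """A record refers to a chromosome absent from the genome index."""


class OverlappingIntervalsError(EpitypeError):
    """bedGraph records overlap, so bin values would be ambiguous."""


class ScaleError(EpitypeError):
    """A track is on the wrong scale for the requested operation."""


class GeometryError(EpitypeError):
    """Bin size, track length or window geometry is inconsistent."""


class RebinError(EpitypeError):
    """Requested rebinning is an upsampling, which is unsupported."""


class ShapeError(EpitypeError):
    """A model input or latent does not match the configured shape."""


class RefAlleleMismatchError(EpitypeError):
    """The variant's stated reference allele disagrees with the genome."""


class StaleCacheError(EpitypeError):
    """A latent cache was produced by a different backbone."""


class TrainingDivergedError(EpitypeError):
    """The loss became non-finite during optimisation."""


class EmptyJoinError(EpitypeError):
    """Two tables to be joined share no identifiers."""


class ConfigError(EpitypeError):
    """A configuration value violates its invariants."""
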