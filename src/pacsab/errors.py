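"""Exception hierarchy for the toolkit."""


class PacsabError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PacsabError):
    """Malformed structure or trajectory file (names the offending line)."""


class IntegrityError(PacsabError):
    """Internally inconsistent file (e.g. declared vs actual atom count)."""


class ModelError(PacsabError):
    """Structure cannot be mapped to the coarse-grained model."""


class SetupError(PacsabError):
    """Rejected two-copy setup (e.g. inter-copy clash)."""


class ConfigError(PacsabError):
    """Invalid simulation configuration."""


class InstabilityError(PacsabError):
    """Integrator blow-up; carries the step and particle index."""

    def __init__(self, message, step=None, particle=None):
        super().__init__(message)
        self.step = step
        self.particle = particle


class SingularityError(PacsabError):
    """Overlapping particles during energy evaluation."""
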