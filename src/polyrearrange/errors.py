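"""Exception hierarchy."""


class PolyrearrangeError(Exception):
    """Base class for package errors."""


class ParseError(PolyrearrangeError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(PolyrearrangeError):
    """Parsed content violates a domain invariant."""


class ConfigError(PolyrearrangeError):
    """Invalid simulation or pipeline configuration."""


class LowCoverageError(PolyrearrangeError):
    """Accession excluded: genome-wide coverage below the required minimum."""


class NoSignalError(PolyrearrangeError):
    """No breakpoint signal (no discordant pairs in the candidate regions)."""
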