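"""Exception hierarchy shared across the pipeline."""


class AmfPipeError(Exception):
    """Base class for all amfpipe errors."""


class ParseError(AmfPipeError):
    """A file did not conform to its declared format."""


class ConfigError(AmfPipeError):
    """An invalid parameter or configuration value was supplied."""


class ValidationError(AmfPipeError):
    """A domain object violated one of its invariants."""
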