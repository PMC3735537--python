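"""Exception hierarchy for circasense."""


class CircasenseError(Exception):
    """Base class for all circasense errors."""


class FormatError(CircasenseError, ValueError):
    """A file or table does not conform to the expected schema."""


class IntegrityError(CircasenseError, ValueError):
    """Input violates a uniqueness or consistency constraint."""


class ConfigurationError(CircasenseError, ValueError):
    """A parameter object is internally inconsistent."""
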