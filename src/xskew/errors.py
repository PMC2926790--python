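"""Exception hierarchy for xskew."""


class XskewError(Exception):
    """Base class for all xskew-specific errors."""


class FormatError(XskewError):
    """A file or table does not conform to the expected layout."""


class DesignError(XskewError):
    """The experimental design cannot support the requested analysis."""


class ParameterError(XskewError):
    """Invalid simulation or estimation parameters."""
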