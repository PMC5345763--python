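"""Exception hierarchy.

Everything raised on bad user input derives from :class:`DceTensorError`
(itself a ``ValueError``) so callers can catch one type at the CLI boundary.
"""


class DceTensorError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(DceTensorError):
    """A parameter is out of its documented range."""


class DimensionError(DceTensorError):
    """Array shapes or geometries are inconsistent."""


class DegenerateInputError(DceTensorError):
    """Input carries too little variation for the requested operation
    (e.g. a constant volume handed to a clustering step)."""


class PipelineError(DceTensorError):
    """A pipeline stage produced an unusable intermediate
    (e.g. an empty region-of-interest mask)."""
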