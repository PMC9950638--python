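"""Exception hierarchy.

``ConfigurationError`` marks a bad run configuration or file schema,
``InputError`` an unusable input file, and ``AnalysisError`` a dataset that
cannot support the requested computation (too few instruments, empty
intersection, degenerate design).
"""


class BidimrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BidimrError):
    pass


class InputError(BidimrError):
    pass


class AnalysisError(BidimrError):
    pass
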