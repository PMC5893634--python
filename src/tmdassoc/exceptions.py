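"""Exception hierarchy for tmdassoc."""


class TmdassocError(Exception):
    """Base class for package errors."""


class ValidationError(TmdassocError, ValueError):
    """Invalid parameter or inconsistent input."""


class SelectionError(TmdassocError, KeyError):
    """An atom selection resolved to no atoms (or a named atom is missing)."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class FormatError(TmdassocError, ValueError):
    """A file could not be parsed in the expected format."""


class ConvergenceError(TmdassocError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class WindowGapError(TmdassocError, ValueError):
    """Neighbouring umbrella windows have no overlapping populated bins."""
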