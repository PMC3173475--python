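"""Package exceptions."""

from __future__ import annotations


class ProtstabError(Exception):
    """Base class for package errors."""


class FitConvergenceError(ProtstabError):
    """A nonlinear least-squares fit failed to converge.

    Carries the last parameter iterate so the caller can inspect where the
    optimizer stalled.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FormatError(ProtstabError):
    """A file could not be parsed; the message names the offending line."""
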