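"""Exception hierarchy shared by all pipeline stages."""


class CtbindError(Exception):
    """Base class for all package errors."""


class ValidationError(CtbindError, ValueError):
    """Input data violates a stage precondition or a type invariant."""


class InsufficientDataError(CtbindError, ValueError):
    """Too few usable points to perform a fit or extraction."""


class InsufficientEvidenceError(CtbindError, ValueError):
    """Fewer evidence fields than the quorum required for a mode verdict."""


class DegenerateCurveError(CtbindError, ValueError):
    """A melting curve with no hyperchromic transition (flat absorbance)."""
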