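"""Exception hierarchy for rbsmeth."""


class RbsmethError(Exception):
    """Base class for all package errors."""


class ValidationError(RbsmethError):
    """Invalid input (bad alphabet, out-of-range parameter, malformed record)."""


class AlignmentError(RbsmethError):
    """Alignment could not be performed (e.g. empty reference set)."""


class QCError(RbsmethError):
    """A library failed a quality gate (spike-in conversion below threshold)."""


class StructureError(RbsmethError):
    """Structural mapping failed (anticodon absent or ambiguously placed)."""


class AssayError(RbsmethError):
    """A methyl-chop / dCAPS assay could not be constructed."""
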