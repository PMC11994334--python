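"""Exception hierarchy for secmdecon.

All package-specific failures derive from :class:`SecmDeconError` so callers
can catch one base class at pipeline boundaries.
"""


class SecmDeconError(Exception):
    """Base class for all secmdecon errors."""


class FormatError(SecmDeconError):
    """A file does not conform to the expected tabular format."""


class RecordValidationError(SecmDeconError):
    """A per-read record violates an invariant (e.g. n_meth > n_cpg)."""


class ParameterError(SecmDeconError, ValueError):
    """An argument is outside its valid domain."""


class UndefinedLevelError(SecmDeconError):
    """A methylation level or distribution is undefined (no informative data).

    Raised instead of silently returning 0: a sample with no covered CpG
    sites has *no* methylation level, which is different from being
    unmethylated.
    """


class InsufficientReadsError(SecmDeconError):
    """A subsampling or mixing request exceeds the available reads."""


class LowQualityError(SecmDeconError):
    """Too little usable signal to produce a call (e.g. < 20 callable autosomes)."""
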