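"""Exception hierarchy shared by all pipeline stages."""


class ZygoctError(Exception):
    """Base class for all errors raised by this package."""


class CtParseError(ZygoctError):
    """A cell in a Ct/intensity table could not be parsed as a number."""


class IntegrityError(ZygoctError):
    """Duplicate keys or internally inconsistent table structure."""


class AnnotationError(ZygoctError):
    """Sample annotation does not match the data matrix or uses unknown labels."""


class ParameterError(ZygoctError):
    """A parameter is outside its documented domain."""


class DegenerateCardError(ZygoctError):
    """A card contributes no detected Ct value, so no median is defined."""


class DegenerateArrayError(ZygoctError):
    """An intensity array has no positive signal, so no median is defined."""


class NormalizationError(ZygoctError):
    """The requested normalizer cannot be applied (e.g. reference gene not detected)."""


class ClusterInputError(ZygoctError):
    """Two samples share no jointly detected assay; their distance is undefined."""
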