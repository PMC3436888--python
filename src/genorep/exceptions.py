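"""Exception hierarchy for genorep."""


class GenorepError(Exception):
    """Base class for all genorep errors."""


class InvalidParameterError(GenorepError, ValueError):
    """A numeric parameter is out of range or non-finite."""


class PanelError(GenorepError, ValueError):
    """SNP panel is malformed or two call vectors are not panel-compatible."""


class DesignError(GenorepError, ValueError):
    """Study-design metadata is inconsistent with the data it describes."""


class FormatError(GenorepError, ValueError):
    """A file being read violates the expected text format."""


class GridAlignmentError(GenorepError, ValueError):
    """A MAF/population-size combination does not yield integer allele counts."""


class UndefinedConcordanceError(GenorepError, ArithmeticError):
    """Concordance requested where the denominator is zero."""


class UndefinedRatioError(GenorepError, ArithmeticError):
    """Odds ratio undefined: a zero cell with the continuity correction disabled."""
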