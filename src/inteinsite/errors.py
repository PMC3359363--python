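"""Exception and warning types raised across the package."""


class InteinSiteError(Exception):
    """Base class for all errors raised by this package."""


class PSSMParseError(InteinSiteError):
    """A PSI-BLAST ASCII PSSM file could not be parsed."""


class StrideParseError(InteinSiteError):
    """A secondary-structure assignment file could not be parsed."""


class CassetteRangeError(InteinSiteError, ValueError):
    """Requested cassette window extends past a sequence terminus."""


class StructureMappingError(InteinSiteError):
    """Structure residues could not be mapped onto extein numbering."""


class AnnotationError(InteinSiteError):
    """A functional-residue annotation set is empty or unmappable."""


class UndefinedRankError(InteinSiteError):
    """A rank is undefined (fewer than two sites to rank against)."""


class DegenerateGeometryError(InteinSiteError):
    """Coordinates are too few or too degenerate for superposition."""


class MissingFeatureError(InteinSiteError, KeyError):
    """A feature required by the active predictor rule is absent."""


class SyntheticParameterError(InteinSiteError, ValueError):
    """Synthetic-case parameters are infeasible or inconsistent."""


class InteinSiteWarning(UserWarning):
    """Base class for warnings emitted by this package."""
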