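"""Structured exceptions raised across the pipeline.

Every stage failure carries enough context (offending SMILES, descriptor
name, column names) for the pipeline driver to report which stage and
which input broke.
"""


class PairQSARError(Exception):
    """Base class for all package errors."""


class SmilesParseError(PairQSARError):
    """SMILES string could not be parsed. Carries the offending string."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        self.code = "parse"
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class MultiComponentError(PairQSARError):
    """Input structure has more than one connected component (salt/mixture)."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        self.code = "multi-component"
        super().__init__(f"multi-component structure: {smiles!r}")


class UnsupportedElementError(PairQSARError):
    """Element outside the partial-charge model's parameter table."""


class NoGeometryError(PairQSARError):
    """A geometric descriptor was requested but no 3D coordinates exist."""


class InvalidDescriptorError(PairQSARError):
    """Descriptor name or parameters outside the supported grammar."""


class SingularDesignError(PairQSARError):
    """Rank-deficient design matrix; names the collinear columns when known."""

    def __init__(self, columns=None):
        self.columns = list(columns) if columns is not None else []
        msg = "singular design matrix"
        if self.columns:
            msg += f"; collinear columns: {self.columns}"
        super().__init__(msg)


class UndefinedStatisticError(PairQSARError):
    """A statistic's denominator is degenerate (zero variance etc.)."""


class AllFilteredError(PairQSARError):
    """Objective feature selection removed every descriptor column."""


class CurationError(PairQSARError):
    """Activity-table curation could not proceed."""


class StageError(PairQSARError):
    """Pipeline stage failure wrapper; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
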