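"""Exception hierarchy shared across the package.

The runner maps these onto process exit codes, so every stage raises one of
the subclasses below rather than bare ValueError.
"""


class PedscoreError(Exception):
    """Base class for all pedscore errors."""


class ValidationError(PedscoreError):
    """Malformed input records (duplicate ids, half-specified parents, ...)."""


class CycleError(ValidationError):
    """Pedigree parent graph contains a cycle."""

    def __init__(self, person_id: str):
        self.person_id = person_id
        super().__init__(f"pedigree cycle detected involving individual {person_id!r}")


class ConfigurationError(PedscoreError):
    """Inconsistent or incomplete run configuration."""


class FormatError(PedscoreError):
    """File does not conform to its declared format."""


class DataError(PedscoreError):
    """Data values are unusable (empty intersection, all SNPs removed, ...)."""


class NumericalError(PedscoreError):
    """Numerical failure (non-PD covariance, non-convergence, singularity)."""

    def __init__(self, message: str, detail=None):
        self.detail = detail
        super().__init__(message)
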