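"""Exception types shared across the pipeline stages."""


class OrthoprioError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OrthoprioError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class InvalidDesignError(OrthoprioError, ValueError):
    """An experimental design is degenerate (e.g. a group with < 2 samples)."""


class MonomorphicSnpError(OrthoprioError, ValueError):
    """A SNP has zero genotype variance where variation is required."""


class EmptyJoinError(OrthoprioError, ValueError):
    """An ortholog join produced no rows."""
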