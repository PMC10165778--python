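"""Exception hierarchy shared across the pipeline."""


class MigbiomeError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(MigbiomeError, ValueError):
    """A synthetic cohort design violates its invariants."""


class FormatError(MigbiomeError, ValueError):
    """An on-disk file is malformed (bad cell, duplicate id, ...)."""


class SchemaError(MigbiomeError, ValueError):
    """A table is missing required columns or has inconsistent ids."""


class ReconciliationError(MigbiomeError, ValueError):
    """Feature/sample id sets of two inputs do not line up."""
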