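"""Exception types shared across the pipeline."""


class SynscreenError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(SynscreenError):
    """An input table does not carry the expected columns."""


class RecordError(SynscreenError):
    """A row of an input table cannot be parsed into a valid well record."""


class DesignError(SynscreenError):
    """Inputs are inconsistent with the screen design (missing keys, mismatched grids)."""
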