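"""Exception hierarchy shared across the pipeline."""


class GlycolectError(Exception):
    """Base class for all package-specific errors."""


class SpotTableFormatError(GlycolectError):
    """A spot table file violates the declared dialect (missing/garbled columns)."""


class PanelMismatchError(GlycolectError):
    """Spot records name lectins that are absent from the active panel."""


class DuplicateSpotError(GlycolectError):
    """Two records claim the same (slide, block, lectin, row, column) address."""


class ManifestError(GlycolectError):
    """A group manifest is malformed or inconsistent."""


class ConfigError(GlycolectError):
    """A simulation or pipeline configuration fails validation."""


class EmptyBlockError(GlycolectError):
    """Every spot of every lectin in a block is flagged bad."""


class DegenerateBlockError(GlycolectError):
    """All net medians in a block are zero; NFIs are undefined."""


class UndefinedRatioError(GlycolectError):
    """The control group's mean NFI is zero; the fold change is undefined."""
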