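"""Exception hierarchy shared across the pipeline."""


class ScmError(Exception):
    """Base class for all pipeline errors."""


class InvariantError(ScmError, ValueError):
    """A data-model invariant was violated (bad input, not a bug downstream)."""


class EmptyRunError(ScmError):
    """An operation produced (or was given) a run with no usable scans."""


class EmptyMatrixError(ScmError):
    """A filter removed every cell or every feature; parameters need review."""


class LayerError(ScmError):
    """A matrix operation was applied at the wrong layer or out of order."""


class LowCoverageError(ScmError):
    """Lock-mass reference ion found in too few scans to estimate an offset."""


class ConfigError(ScmError):
    """Pipeline configuration is malformed (unknown keys, bad values)."""
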