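"""Exception hierarchy for sparsebeam."""


class SparsebeamError(Exception):
    """Base class for all sparsebeam errors."""


class GeometryError(SparsebeamError):
    """Invalid probe geometry (element count, pitch, ordering)."""


class GridError(SparsebeamError):
    """Invalid reconstruction grid definition."""


class SubsetError(SparsebeamError):
    """Invalid element-subset request."""


class SamplingError(SparsebeamError):
    """Sampling rate incompatible with the requested pulse (Nyquist)."""


class TruncationError(SparsebeamError):
    """A waveform would fall (partly) outside the configured time window."""


class SolverError(SparsebeamError):
    """FISTA / power-iteration failure (divergence, dimension mismatch)."""


class UnderResolvedError(SparsebeamError):
    """Fewer distinct peaks found than expected — the programmatic
    definition of 'not resolved'."""


class MetricError(SparsebeamError):
    """Undefined metric (e.g. correlation of an identically-zero image)."""


class ConfigError(SparsebeamError):
    """Configuration file violates the schema."""
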