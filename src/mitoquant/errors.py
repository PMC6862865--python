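"""Exception types shared across the pipeline."""


class MitoquantError(Exception):
    """Base class for all pipeline errors."""


class ScheduleError(MitoquantError):
    """Invalid injection schedule (wrong phase order or nonpositive cycle counts)."""


class GenerationError(MitoquantError):
    """Synthetic generation failed (e.g. infeasible object packing)."""


class SummaryError(MitoquantError):
    """A per-well summary could not be computed (e.g. missing phase)."""


class NormalizationError(MitoquantError):
    """Nonpositive or missing normalization signal."""


class ReportError(MitoquantError):
    """Report assembly failed (e.g. conflicting group labels)."""
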