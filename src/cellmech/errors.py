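"""Exception hierarchy for the cellmech pipeline."""


class CellMechError(Exception):
    """Base class for all cellmech errors."""


class InvalidConfigError(CellMechError, ValueError):
    """A generator or fit configuration violates its invariants."""


class ProcessingError(CellMechError):
    """A curve-processing step cannot run on the given data."""


class NoContactError(ProcessingError):
    """No contact point improves on the flat (no-indentation) model."""


class FitError(CellMechError):
    """A model fit failed or has too few points."""


class NoIC50Error(FitError):
    """The viability data carry no resolvable dose-response midpoint."""


class InsufficientDataError(CellMechError):
    """Fewer observations than the operation's stated minimum."""


class GenerationError(CellMechError):
    """Synthetic-data generation failed (e.g. truncated sampling)."""
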