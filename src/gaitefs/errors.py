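"""Exception hierarchy for gaitefs.

All errors derive from :class:`GaitEfsError` so callers can catch the
package's failures with a single ``except`` clause while still
distinguishing parameter problems from degenerate inputs.
"""


class GaitEfsError(Exception):
    """Base class for all gaitefs errors."""


class ParameterError(GaitEfsError, ValueError):
    """A configuration or generator parameter violates its constraints."""


class TrialTooShortError(GaitEfsError, ValueError):
    """A trial is too short for the requested operation (e.g. trimming)."""


class DegenerateInputError(GaitEfsError, ValueError):
    """Input carries no usable signal (constant sequence, all-zero IMFs, ...)."""


class InsufficientGaitError(GaitEfsError, ValueError):
    """Too few gait events were detected to segment the trial."""


class UndefinedEntropyError(DegenerateInputError):
    """Sample entropy is undefined: no template matches at one of the lengths."""


class FoldConstructionError(GaitEfsError, ValueError):
    """Cross-validation folds could not be built (e.g. single-class training fold)."""
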