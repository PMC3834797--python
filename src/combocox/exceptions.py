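"""Exception hierarchy for combocox."""


class ComboCoxError(Exception):
    """Base class for all combocox errors."""


class InputError(ComboCoxError, ValueError):
    """Malformed or inconsistent user input (shapes, dtypes, schemas)."""


class DegenerateDataError(ComboCoxError, ValueError):
    """Data that makes the requested computation undefined (e.g. no events)."""


class FittingError(ComboCoxError, RuntimeError):
    """An optimization step produced an impossible result (e.g. a nested
    model with higher likelihood than its superset)."""


class PathError(ComboCoxError, RuntimeError):
    """The path-following loop could not make progress."""
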