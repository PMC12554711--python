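"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument violates a precondition (range, sign, membership)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (e.g. zero variance)."""


class CohortIntegrityError(RuntimeError):
    """A cohort is incomplete or inconsistent (missing session, duplicate subject)."""


class FixtureIntegrityError(RuntimeError):
    """A packaged data fixture fails its integrity checks."""
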