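"""Exception hierarchy for the MR pipeline."""


class MRError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(MRError, ValueError):
    """Input data violates a container invariant."""


class EmptyInputError(MRError, ValueError):
    """A table or selection step produced zero usable rows."""


class NoOverlapError(MRError, ValueError):
    """Exposure and outcome share no variant identifiers."""


class MissingLDError(MRError, KeyError):
    """A candidate instrument is absent from the supplied LD matrix."""


class InsufficientInstrumentsError(MRError, ValueError):
    """Too few instruments for the requested estimator."""


class DegenerateInputError(MRError, ValueError):
    """Inputs make the requested quantity undefined (e.g. all bx = 0)."""
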