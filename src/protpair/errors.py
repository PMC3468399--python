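"""Exception hierarchy for protpair."""


class ProtPairError(Exception):
    """Base class for all protpair errors."""


class ValidationError(ProtPairError):
    """An input table violates a structural invariant."""


class InsufficientSamplesError(ProtPairError):
    """A peptide pair has fewer than two usable samples in one class.

    Signals that the pair cannot be scored; callers enumerate past it
    rather than aborting a scan.
    """


class DegenerateSpreadError(ProtPairError):
    """A ratio vector has zero standard deviation ("degenerate-spread").

    The discriminability index denominator vanishes, so the pair is
    excluded from ranking instead of being assigned an infinite score.
    """

    reason = "degenerate-spread"


class NoScorablePairsError(ProtPairError):
    """No peptide pair in the table survived the usability rules."""
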