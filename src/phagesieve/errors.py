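"""Exception types shared across the package."""


class CapabilityError(RuntimeError):
    """A required external capability (e.g. the blastn executable) is unavailable.

    The library itself stays fully usable on precomputed hit files; only the
    operations that must shell out to an aligner raise this.
    """


class AlignerError(RuntimeError):
    """An external aligner invocation failed (nonzero exit)."""


class HitParseError(ValueError):
    """A tabular hit line could not be parsed; the message names the line number."""
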