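"""Pipeline error type with stable machine-readable codes."""


class StoryEncError(ValueError):
    """Error raised by any pipeline stage.

    Parameters
    ----------
    code
        Stable, hyphenated identifier (e.g. ``"empty-context"``,
        ``"collinear-design"``) that callers can match on.
    message
        Human-readable detail; defaults to the code.
    """

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)
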