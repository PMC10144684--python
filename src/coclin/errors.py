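"""Exception types shared across the toolkit."""


class CoclinError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(CoclinError, ValueError):
    """An input violates a documented precondition."""


class UndefinedResponseError(CoclinError, ValueError):
    """Response rate requested for a zero baseline value."""


class EmptyOverlapError(CoclinError, ValueError):
    """Gene-set harmonization found no shared symbols."""
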