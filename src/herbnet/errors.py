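"""Exception hierarchy shared across modules."""


class HerbnetError(Exception):
    """Base class for all package errors."""


class SchemaError(HerbnetError):
    """An input table is missing a required column or has a malformed cell."""


class ReferentialError(HerbnetError):
    """A record references an identifier absent from its parent table."""


class DegenerateCorpusError(HerbnetError):
    """The corpus cannot support the requested statistic (e.g. all
    prescriptions are singletons, so no herb pair ever co-occurs)."""


class DegenerateGraphError(HerbnetError):
    """The assembled graph has no herb-herb edges to learn from."""


class DivergenceError(HerbnetError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class ComparisonError(HerbnetError):
    """A two-group comparison was requested with an empty group."""
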