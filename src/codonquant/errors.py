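"""Exception hierarchy for codonquant."""


class CodonQuantError(Exception):
    """Base class for all codonquant errors."""


class ConfigurationError(CodonQuantError):
    """A configuration object violates its invariants."""


class ValidationError(CodonQuantError):
    """An input record or table violates a stated contract."""


class MappingError(CodonQuantError):
    """A peptide could not be located in its assigned protein."""

    def __init__(self, message: str, peptide: str | None = None,
                 protein_id: str | None = None):
        super().__init__(message)
        self.peptide = peptide
        self.protein_id = protein_id


class IntegrityError(CodonQuantError):
    """Coding sequence and protein databases are out of sync."""


class DegenerateDesignError(CodonQuantError):
    """A statistical model cannot be fit on a degenerate design."""
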