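"""Exception hierarchy for echoscale."""


class EchoscaleError(Exception):
    """Base class for all package-specific errors."""


class NewickError(EchoscaleError):
    """Malformed or invalid Newick input (unbalanced string, duplicate tips,
    negative or missing branch lengths)."""


class TraitTableError(EchoscaleError):
    """Missing columns, unparseable cells or non-positive trait values."""


class HarmonizationError(EchoscaleError):
    """Tree and trait table cannot be reconciled (e.g. empty species overlap)."""


class ModelError(EchoscaleError):
    """Invalid model specification or degenerate design."""


class NumericalError(EchoscaleError):
    """Singular covariance, rank deficiency or optimizer failure."""
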