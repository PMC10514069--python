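"""Exception hierarchy for cscpair.

Every input-contract violation raises a distinct, named error so callers
(and the CLI) can report precisely what was wrong with the data.
"""


class CSCPairError(Exception):
    """Base class for all cscpair errors."""


class DimensionMismatchError(CSCPairError):
    """Matrix dimensions disagree with the gene/cell sidecars or labels."""


class NegativeEntryError(CSCPairError):
    """An expression matrix contains a negative value."""


class DuplicateIDError(CSCPairError):
    """Gene or cell identifiers are not unique."""


class MissingColumnError(CSCPairError):
    """A required column is absent from a table."""


class EmptyTableError(CSCPairError):
    """A table that must contain at least one row is empty."""


class CellTypeError(CSCPairError):
    """A requested cell type is absent or has too few cells."""


class EmptyInputError(CSCPairError):
    """Filtering left an empty ligand or receptor matrix."""


class NoCSCPError(CSCPairError):
    """Consensus clustering produced no joint cluster with both a sender
    and a receiver side, so no sub-crosstalk pair can be formed."""


class ZeroDifferenceError(CSCPairError):
    """All paired differences are zero; the signed-rank test is undefined."""
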