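"""Exception hierarchy for the anca package."""


class AncaError(Exception):
    """Base class for all anca errors."""


class ParseError(AncaError):
    """A structure or table file could not be parsed."""


class FetchError(AncaError):
    """A structure could not be retrieved from the PDB."""


class EmptyStructureError(AncaError):
    """The input contains no polymer residues usable for network building."""


class MissingWeightError(AncaError):
    """A node-weight specification does not cover every network node."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "no weight resolved for residues: "
            + ", ".join(str(m) for m in self.missing)
        )


class TableValidationError(AncaError):
    """An energy table violates symmetry or completeness requirements."""


class LookupError_(AncaError):
    """A residue type/state pair is absent from the energy table."""


class EmptyNetworkError(AncaError):
    """A builder produced a network with no nodes."""


class ContractViolation(AncaError):
    """An operation was called with inputs outside its contract."""
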