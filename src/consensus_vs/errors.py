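"""Exception hierarchy shared across stages."""


class ConsensusVSError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(ConsensusVSError):
    """A chemical record could not be parsed; carries the offending id."""

    def __init__(self, record_id: str, detail: str = ""):
        self.record_id = record_id
        msg = f"could not parse record {record_id!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ContractViolationError(ConsensusVSError, ValueError):
    """An operation was called outside its documented preconditions."""


class FormatError(ConsensusVSError):
    """An input table or file does not match the expected layout."""
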