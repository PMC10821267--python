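"""Exception hierarchy shared across the package."""


class HlaSeqError(Exception):
    """Base class for all hlaseq errors."""


class ParseError(HlaSeqError):
    """A string or file did not conform to its expected grammar."""


class DataError(HlaSeqError):
    """Input data violates a contract (duplicates, bad alphabet, missing records)."""


class SolverError(HlaSeqError):
    """The ILP solver failed to produce a usable solution."""
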