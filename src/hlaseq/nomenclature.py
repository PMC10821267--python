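"""HLA allele nomenclature.

Each HLA allele carries a unique name of the form ``LOCUS*f1:f2:f3:f4`` with up
to four colon-separated numeric fields: antigen group, protein, synonymous
coding change and non-coding change, optionally followed by an expression
suffix letter (e.g. ``N`` for null alleles).  "Two-field resolution" names the
allele at the protein level and is the resolution commonly used clinically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

#: Recognized expression-status suffix letters (null, low, secreted,
#: cytoplasm-restricted, aberrant, questionable).
EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

_FIELD_RE = re.compile(r"^[0-9]+$")


@dataclass(frozen=True)
class AlleleName:
    """Parsed HLA allele name.

    Attributes
    ----------
    locus:
        Gene name as written before the ``*`` separator (e.g. ``HLA-A``).
    fields:
        One to four numeric field codes, kept as strings to preserve
        zero-padding (``("01", "01")``).
    suffix:
        Optional expression-status letter attached to the last field.
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.locus:
            raise ParseError("allele name has an empty locus")
        if not 1 <= len(self.fields) <= 4:
            raise ParseError(
                f"allele name must have 1-4 fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not _FIELD_RE.match(f):
                raise ParseError(f"non-numeric allele field {f!r}")
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise ParseError(f"unknown expression suffix {self.suffix!r}")

    @property
    def resolution(self) -> int:
        """Number of fields present."""
        return len(self.fields)

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix or ''}"

    @property
    def numeric_key(self) -> tuple:
        """Sort key ordering alleles by locus then numeric field values.

        Used wherever the "lowest numbered" allele must be picked (G-group
        naming).
        """
        return (self.locus, tuple(int(f) for f in self.fields), self.suffix or "")


def parse_allele_name(raw: str) -> AlleleName:
    """Parse ``LOCUS*f1:f2[:f3[:f4]][suffix]`` into an :class:`AlleleName`.

    Raises :class:`ParseError` naming the offending token on malformed input
    (missing ``*``, empty or non-numeric field).
    """
    raw = raw.strip()
    if "*" not in raw:
        raise ParseError(f"allele name {raw!r} lacks the '*' locus separator")
    locus, _, rest = raw.partition("*")
    if not locus:
        raise ParseError(f"allele name {raw!r} has an empty locus")
    if not rest:
        raise ParseError(f"allele name {raw!r} has no fields after '*'")
    suffix: str | None = None
    if rest[-1].isalpha():
        suffix = rest[-1]
        rest = rest[:-1]
        if suffix not in EXPRESSION_SUFFIXES:  # suffixes are uppercase letters
            raise ParseError(f"unknown expression suffix {suffix!r} in {raw!r}")
    fields = rest.split(":")
    for f in fields:
        if not _FIELD_RE.match(f):
            raise ParseError(f"non-numeric field {f!r} in allele name {raw!r}")
    if len(fields) > 4:
        raise ParseError(f"allele name {raw!r} has more than four fields")
    return AlleleName(locus=locus, fields=tuple(fields), suffix=suffix)


def truncate_resolution(name: AlleleName, n_fields: int) -> AlleleName:
    """Return *name* restricted to its first *n_fields* fields.

    The expression suffix is attached to the last field, so it is dropped
    whenever truncation removes fields.  Truncation never pads: asking for
    more fields than available is an error.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if n_fields > len(name.fields):
        raise ValueError(
            f"cannot truncate {name} to {n_fields} fields: only "
            f"{len(name.fields)} available"
        )
    if n_fields == len(name.fields):
        return name
    return AlleleName(locus=name.locus, fields=name.fields[:n_fields], suffix=None)
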