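"""Categorized exceptions used across the package.

Every error raised by the library carries a ``category`` attribute so the
command-line layer can report failures uniformly as
``[<category>] <message>``.  Categories: ``format`` (malformed input files),
``value`` (invalid numeric or parameter values), ``key`` (reference to an
unknown gene/phenotype/term), ``capacity`` (size limits).
"""

from __future__ import annotations


class PhenoArcError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(PhenoArcError):
    """Malformed input text: ragged rows, bad field counts, length mismatches."""

    category = "format"


class DuplicateRecordError(FormatError):
    """The same (gene, phenotype) pair appears more than once in a dataset file."""


class DataValueError(PhenoArcError, ValueError):
    """A value is out of range or otherwise invalid (e.g. p-value outside [0, 1])."""

    category = "value"


class UnknownEntityError(PhenoArcError, KeyError):
    """A gene, phenotype or term was referenced that the dataset does not contain."""

    category = "key"

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return Exception.__str__(self)


class CapacityError(PhenoArcError):
    """A computed object exceeds a hard size limit (e.g. the 500-node network cap)."""

    category = "capacity"
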