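"""Exception hierarchy.

``ValidationError`` marks malformed user input (CLI exit code 2);
``DesignError`` and ``AssemblyError`` mark infeasible designs or failed
in-silico assemblies (CLI exit code 1).
"""


class GgmutError(Exception):
    """Base class for all package errors."""


class ValidationError(GgmutError, ValueError):
    """Invalid input: bad characters, broken reading frame, bad spec."""


class DesignError(GgmutError):
    """A design request that cannot be satisfied (too-short fragment,
    no valid overhang window, exhausted template, ...)."""


class UndomesticatableSiteError(DesignError):
    """No single-codon synonymous substitution removes an internal
    type IIS recognition site."""


class AssemblyError(GgmutError):
    """In-silico PCR / digestion / ligation failure."""


class QqcError(GgmutError):
    """Chromatogram parsing or read-mapping failure."""
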