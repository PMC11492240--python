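"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (click),
:class:`ValidationError` subclasses exit 3, anything else raised by the
pipeline exits 4.
"""


class ReinetError(Exception):
    """Base class for all package errors."""


class ParseError(ReinetError):
    """A structure/topology/parameter file could not be parsed."""


class EmptyInputError(ParseError):
    """Input contained no protein residues (or no frames)."""


class ShapeError(ReinetError):
    """Atom counts between topology and coordinates disagree."""


class ParameterLookupError(ReinetError):
    """An atom type has no entry in the nonbonded parameter table."""


class SingularityError(ReinetError):
    """Pair energy requested at zero interatomic distance."""


class ValidationError(ReinetError):
    """Inputs are structurally valid but violate a contract
    (nonpositive edge cost, unnormalized profile, unknown label...)."""
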