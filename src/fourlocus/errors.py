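"""Exception hierarchy and process exit codes.

Validation problems (bad input data, malformed files, impossible specs) exit
with code 2; statistically degenerate situations (empty groups, zero margins)
exit with code 3.
"""


class FourLocusError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FourLocusError):
    """Input data violates a contract (bad allele, duplicate id, bad group)."""

    exit_code = 2


class FormatError(ValidationError):
    """A file is structurally unreadable (missing column, bad VCF site)."""


class SpecError(ValidationError):
    """A simulation spec or analysis config is invalid."""


class EmptyGroupError(FourLocusError):
    """A computation requires at least one usable sample and found none."""

    exit_code = 3


class DegenerateTableError(FourLocusError):
    """A contingency table has a zero margin or zero cell where forbidden."""

    exit_code = 3


class DerivationError(FourLocusError):
    """Risk-model derivation cannot run (reference combination absent)."""

    exit_code = 3


class CountConsistencyWarning(UserWarning):
    """Reconstructed integer counts do not sum to the stated group size."""
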