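"""The four biallelic SNP loci of the asthma risk-genotype panel.

Each locus carries a designated risk allele; the genotype homozygous for it
(the "risk homozygote") is the unit the four-locus model counts. The panel is
fixed: ADRB2 rs1042713 (A/G, risk A), IL4 rs2243250 (T/C, risk T),
FCER1B rs569108 (A/G, risk G) and IL13 rs20541 (A/G, risk G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

#: Tokens accepted as a missing genotype call.
MISSING_TOKENS = frozenset({"", "NA", "na", "N/A", ".", "./.", ".|.", "--"})


@dataclass(frozen=True)
class Locus:
    """One biallelic SNP with a designated risk allele.

    ``allele_1``/``allele_2`` fix a declaration order used to canonicalize
    heterozygotes (the published tables write both "GA" and "AG").
    """

    gene: str
    rs_id: str
    allele_1: str
    allele_2: str
    risk_allele: str

    def __post_init__(self) -> None:
        for a in (self.allele_1, self.allele_2, self.risk_allele):
            if len(a) != 1 or a not in "ACGT":
                raise ValidationError(f"{self.rs_id}: invalid allele {a!r}")
        if self.allele_1 == self.allele_2:
            raise ValidationError(f"{self.rs_id}: alleles must differ")
        if self.risk_allele not in (self.allele_1, self.allele_2):
            raise ValidationError(
                f"{self.rs_id}: risk allele {self.risk_allele!r} is not one of "
                f"{self.allele_1}/{self.allele_2}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_1, self.allele_2)

    @property
    def nonrisk_allele(self) -> str:
        return self.allele_2 if self.risk_allele == self.allele_1 else self.allele_1

    @property
    def risk_homozygote(self) -> tuple[str, str]:
        return (self.risk_allele, self.risk_allele)


@dataclass(frozen=True)
class Genotype:
    """An unordered allele pair at one locus, or a missing call.

    Canonical form sorts the pair by the locus's allele declaration order,
    so GA and AG at IL13 are the same heterozygote.
    """

    locus: Locus
    alleles: Optional[tuple[str, str]] = field(default=None)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_heterozygote(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_risk_homozygote(self) -> bool:
        """True iff both alleles are the locus's risk allele."""
        return self.alleles == self.locus.risk_homozygote

    def __str__(self) -> str:
        return "NA" if self.alleles is None else "".join(self.alleles)


def normalize_genotype(raw: str, locus: Locus, context: str = "") -> Genotype:
    """Parse a raw genotype string into canonical form.

    Accepts two-character calls in either order ("GA" == "AG"), optional
    "/" or "|" separators, and the missing tokens in :data:`MISSING_TOKENS`.
    Raises :class:`ValidationError` for characters outside the locus alphabet.
    """
    token = raw.strip()
    if token in MISSING_TOKENS:
        return Genotype(locus, None)
    token = token.replace("/", "").replace("|", "").upper()
    if len(token) != 2:
        raise ValidationError(
            f"{context + ': ' if context else ''}{locus.rs_id}: "
            f"cannot parse genotype {raw!r}"
        )
    for ch in token:
        if ch not in locus.alleles:
            raise ValidationError(
                f"{context + ': ' if context else ''}{locus.rs_id}: "
                f"allele {ch!r} not in {locus.allele_1}/{locus.allele_2}"
            )
    order = {locus.allele_1: 0, locus.allele_2: 1}
    pair = tuple(sorted(token, key=order.__getitem__))
    return Genotype(locus, pair)  # type: ignore[arg-type]


ADRB2 = Locus("ADRB2", "rs1042713", "A", "G", "A")
IL4 = Locus("IL4", "rs2243250", "T", "C", "T")
FCER1B = Locus("FCER1B", "rs569108", "A", "G", "G")
IL13 = Locus("IL13", "rs20541", "A", "G", "G")

#: The panel in genotype-table column order.
PANEL: tuple[Locus, ...] = (ADRB2, IL4, FCER1B, IL13)
LOCI_BY_RS = {locus.rs_id: locus for locus in PANEL}
LOCI_BY_GENE = {locus.gene: locus for locus in PANEL}
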