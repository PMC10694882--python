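"""Gene-counting genotype and allele frequency estimation.

With genotype counts N_AA, N_AB, N_BB at a biallelic locus (orientation fixed
so that allele "A" is the locus's designated risk allele), the gene-counting
estimators are

    freq(A)  = (N_AA + N_AB/2) / N        N = N_AA + N_AB + N_BB
    freq(B)  = (N_BB + N_AB/2) / N
    freq(AA) = N_AA / N,  etc.

No Hardy-Weinberg assumption is made anywhere in this module: frequencies are
plain counting estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort, Group
from .errors import EmptyGroupError, ValidationError
from .loci import Locus


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one locus, risk-allele orientation.

    ``n_aa`` counts risk homozygotes, ``n_ab`` heterozygotes and ``n_bb``
    non-risk homozygotes.
    """

    locus: Locus
    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_ab, self.n_bb)


@dataclass(frozen=True)
class AlleleFreqs:
    locus: Locus
    freq_a: float  # risk allele
    freq_b: float
    n_individuals: int

    def percent(self) -> tuple[str, str]:
        """The two frequencies as percentage strings, 2 decimals."""
        return (f"{self.freq_a * 100:.2f}%", f"{self.freq_b * 100:.2f}%")


@dataclass(frozen=True)
class GenotypeFreqs:
    locus: Locus
    freq_aa: float
    freq_ab: float
    freq_bb: float

    def percent(self) -> tuple[str, str, str]:
        return tuple(f"{f * 100:.2f}%"  # type: ignore[return-value]
                     for f in (self.freq_aa, self.freq_ab, self.freq_bb))


def genotype_counts(cohort: Cohort, group: Group, locus: Locus) -> GenotypeCounts:
    """Count risk-hom / het / other-hom genotypes in one group at one locus.

    Samples with a missing call at ``locus`` are excluded. Raises
    :class:`EmptyGroupError` when no non-missing genotype exists.
    """
    n_aa = n_ab = n_bb = 0
    for sample in cohort.group_samples(group):
        g = sample.genotype(locus)
        if g.is_missing:
            continue
        if g.is_heterozygote:
            n_ab += 1
        elif g.is_risk_homozygote:
            n_aa += 1
        else:
            n_bb += 1
    if n_aa + n_ab + n_bb == 0:
        raise EmptyGroupError(
            f"no non-missing {locus.rs_id} genotypes in {group.value} group "
            f"of cohort {cohort.name!r}"
        )
    return GenotypeCounts(locus, n_aa, n_ab, n_bb)


def allele_frequencies(counts: GenotypeCounts) -> AlleleFreqs:
    """Gene-counting allele frequencies: freq_a = (N_AA + N_AB/2) / N."""
    n = counts.total
    if n == 0:
        raise EmptyGroupError(f"{counts.locus.rs_id}: zero genotypes")
    freq_a = (counts.n_aa + counts.n_ab / 2.0) / n
    freq_b = (counts.n_bb + counts.n_ab / 2.0) / n
    return AlleleFreqs(counts.locus, freq_a, freq_b, n)


def genotype_frequencies(counts: GenotypeCounts) -> GenotypeFreqs:
    """Genotype frequencies: each count over the non-missing total."""
    n = counts.total
    if n == 0:
        raise EmptyGroupError(f"{counts.locus.rs_id}: zero genotypes")
    return GenotypeFreqs(counts.locus, counts.n_aa / n, counts.n_ab / n,
                         counts.n_bb / n)
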