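"""Case-control contingency tables and association statistics.

Implements the statistics the study design calls for: Pearson chi-square
(optionally Yates-corrected), the Fisher exact test for sparse 2x2 tables,
the odds ratio with a Woolf (log-normal) confidence interval, a two-sample
t-test from summary statistics, and a normal-approximation rank-sum utility.

Allele-count tables support two conventions. ``two_n`` counts chromosomes
(2*N_AA + N_AB risk alleles per group) and is the statistically conventional
choice. ``per_individual`` counts allele frequency times the number of
individuals (N_AA + N_AB/2, possibly non-integral); its Pearson statistic is
exactly half the ``two_n`` statistic and matches the chi-square values some
published reports print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, ValidationError
from .freq import GenotypeCounts, allele_frequencies

AlleleConvention = Literal["two_n", "per_individual"]


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled group-by-category count table (entries may be non-integral)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("table shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("contingency table needs >=2 rows and columns")
        if np.any(counts < 0):
            raise ValidationError("negative cell count")

    @property
    def is_integral(self) -> bool:
        return bool(np.allclose(self.counts, np.round(self.counts)))

    def expected(self) -> np.ndarray:
        """Margin-product expected counts under independence."""
        total = self.counts.sum()
        if total == 0:
            raise DegenerateTableError("empty table")
        return np.outer(self.counts.sum(axis=1), self.counts.sum(axis=0)) / total


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    method: Literal["pearson", "pearson_yates", "fisher"]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- SD summary of a continuous variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("summary stats need n >= 2")
        if self.sd < 0:
            raise ValidationError("negative standard deviation")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variant: Literal["pooled", "welch"]


def genotype_table(case: GenotypeCounts, control: GenotypeCounts) -> ContingencyTable:
    """2x3 genotype table (rows asthma/control; columns AA, AB, BB,
    risk-allele orientation)."""
    if case.locus != control.locus:
        raise ValidationError("case and control counts are for different loci")
    a = case.locus.risk_allele
    b = case.locus.nonrisk_allele
    return ContingencyTable(
        row_labels=("asthma", "control"),
        col_labels=(a + a, a + b, b + b),
        counts=np.array([case.as_tuple(), control.as_tuple()], dtype=float),
    )


def allele_table(case: GenotypeCounts, control: GenotypeCounts,
                 convention: AlleleConvention = "two_n") -> ContingencyTable:
    """2x2 allele-count table under the chosen counting convention."""
    if case.locus != control.locus:
        raise ValidationError("case and control counts are for different loci")
    rows = []
    for counts in (case, control):
        if convention == "two_n":
            n_a = 2.0 * counts.n_aa + counts.n_ab
            n_b = 2.0 * counts.n_bb + counts.n_ab
        elif convention == "per_individual":
            f = allele_frequencies(counts)
            n_a = f.freq_a * counts.total
            n_b = f.freq_b * counts.total
        else:
            raise ValidationError(f"unknown allele convention {convention!r}")
        rows.append((n_a, n_b))
    return ContingencyTable(
        row_labels=("asthma", "control"),
        col_labels=(case.locus.risk_allele, case.locus.nonrisk_allele),
        counts=np.array(rows, dtype=float),
    )


def pearson_chi2(table: ContingencyTable, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a labelled table.

    ``yates`` applies the 0.5 continuity correction (2x2 tables only).
    Raises :class:`DegenerateTableError` when a row or column margin is zero.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("zero margin: table is degenerate")
    if yates and counts.shape != (2, 2):
        raise ValidationError("Yates correction applies to 2x2 tables only")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=yates)
    return ChiSquareResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        method="pearson_yates" if yates else "pearson",
    )


def fisher_exact(table: ContingencyTable) -> ChiSquareResult:
    """Two-tailed Fisher exact test on an integral 2x2 table.

    The two-tailed p sums hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one. The
    ``statistic`` field carries the observed table's hypergeometric
    probability. Non-integral tables (the per-individual allele convention)
    are rejected: use two_n chromosome counts for exact tests.
    """
    if table.counts.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    if not table.is_integral:
        raise ValidationError(
            "Fisher exact test needs integer counts; build the allele table "
            "with convention='two_n'"
        )
    counts = np.round(table.counts).astype(int)
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    a = counts[0, 0]
    prob = stats.hypergeom.pmf(a, counts.sum(), counts[0].sum(),
                               counts[:, 0].sum())
    return ChiSquareResult(statistic=float(prob), df=1, p_value=float(p),
                           method="fisher")


def odds_ratio_ci(table: ContingencyTable, alpha: float = 0.05,
                  haldane: bool = False) -> ORResult:
    """Odds ratio with Woolf (log-normal) confidence interval.

    Rows are (case, control), columns (exposed, unexposed):
    OR = ad/bc, CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    A zero cell raises :class:`DegenerateTableError` unless ``haldane`` opts
    in to the Haldane-Anscombe +0.5 correction on every cell.
    """
    if table.counts.shape != (2, 2):
        raise ValidationError("odds ratio requires a 2x2 table")
    a, b = table.counts[0]
    c, d = table.counts[1]
    if min(a, b, c, d) <= 0:
        if not haldane:
            raise DegenerateTableError(
                "zero cell: odds ratio undefined (pass haldane=True for the "
                "+0.5 Haldane-Anscombe correction)"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return ORResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
    )


def t_test_from_summary(a: SummaryStats, b: SummaryStats,
                        variant: Literal["pooled", "welch"] = "pooled"
                        ) -> TTestResult:
    """Two-sample t-test from mean/SD/n summaries, two-tailed."""
    if a.sd <= 0 or b.sd <= 0:
        raise ValidationError("t-test requires positive standard deviations")
    equal_var = variant == "pooled"
    stat, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                         equal_var=equal_var)
    if equal_var:
        df = float(a.n + b.n - 2)
    else:  # Welch-Satterthwaite
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(statistic=float(stat), df=df, p_value=float(p),
                       variant=variant)


def rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney rank-sum test (normal approximation, tie-corrected).

    Utility for non-normal continuous comparisons; returns (U, two-tailed p).
    """
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def choose_test(table: ContingencyTable, yates: bool = False) -> ChiSquareResult:
    """Automatic test selection for a 2x2 table.

    Fisher exact when any margin-expected count is below 5 (and the table is
    integral), otherwise Pearson. Larger tables always use Pearson.
    """
    if table.counts.shape == (2, 2) and table.is_integral:
        if np.any(table.expected() < 5):
            return fisher_exact(table)
    return pearson_chi2(table, yates=yates)
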