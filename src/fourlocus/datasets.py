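"""Built-in published summary data for the Han and Kazak pediatric cohorts.

The original case-control study released no per-child data; what it printed
are group sizes, per-locus genotype percentage distributions, age and sex
demographics, and high/low risk-class counts. This module encodes those
summaries verbatim (in the printed genotype column order) and converts them
into the package's risk-oriented count objects, simulation specs and
deterministic reference cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .association import ContingencyTable, SummaryStats
from .cohort import Cohort, Group
from .cohort_io import reconstruct_counts
from .freq import GenotypeCounts
from .loci import LOCI_BY_RS, normalize_genotype
from .simulate import SimulationSpec, cohort_from_counts, spec_from_counts

_GROUPS = (Group.ASTHMA, Group.CONTROL)


@dataclass(frozen=True)
class GroupDemographics:
    n_male: int
    n_female: int
    age: SummaryStats

    @property
    def n(self) -> int:
        return self.n_male + self.n_female


@dataclass(frozen=True)
class StudySummary:
    """Published summary statistics for one nationality's two-group cohort."""

    name: str
    n_case: int
    n_control: int
    #: rs_id -> (printed genotype column labels, {group: printed percentages})
    genotype_pct: Mapping[str, tuple[tuple[str, str, str],
                                     Mapping[Group, tuple[float, float, float]]]]
    demographics: Mapping[Group, GroupDemographics]
    #: (high, low) risk-class counts per group, as published
    risk_counts: Mapping[Group, tuple[int, int]]

    def group_size(self, group: Group) -> int:
        return self.n_case if group == Group.ASTHMA else self.n_control

    def genotype_counts(self) -> dict[Group, dict[str, GenotypeCounts]]:
        """Reconstructed integer genotype counts, risk-allele orientation."""
        out: dict[Group, dict[str, GenotypeCounts]] = {}
        for group in _GROUPS:
            n = self.group_size(group)
            per_locus = {}
            for rs_id, (labels, pct_by_group) in self.genotype_pct.items():
                locus = LOCI_BY_RS[rs_id]
                raw = reconstruct_counts(pct_by_group[group], n)
                oriented = {"aa": 0, "ab": 0, "bb": 0}
                for label, count in zip(labels, raw):
                    g = normalize_genotype(label, locus)
                    key = ("ab" if g.is_heterozygote
                           else "aa" if g.is_risk_homozygote else "bb")
                    oriented[key] += int(count)
                per_locus[rs_id] = GenotypeCounts(locus, oriented["aa"],
                                                  oriented["ab"], oriented["bb"])
            out[group] = per_locus
        return out

    def simulation_spec(self, seed: int = 0) -> SimulationSpec:
        """Simulation spec matching the published distributions exactly."""
        demo = {
            group: {
                "male_prob": d.n_male / d.n,
                "age_mean": d.age.mean,
                "age_sd": d.age.sd,
            }
            for group, d in self.demographics.items()
        }
        return spec_from_counts(self.genotype_counts(), demographics=demo,
                                cohort_name=self.name, seed=seed)

    def reference_cohort(self) -> Cohort:
        """Deterministic cohort realizing the reconstructed counts exactly.

        Valid for per-locus frequency and association analyses; its
        cross-locus structure is artificial (see
        :func:`fourlocus.simulate.cohort_from_counts`).
        """
        return cohort_from_counts(self.name, self.genotype_counts())

    def risk_table(self) -> ContingencyTable:
        """Published high/low risk-class counts as a 2x2 table."""
        return ContingencyTable(
            row_labels=("asthma", "control"), col_labels=("high", "low"),
            counts=np.array([self.risk_counts[Group.ASTHMA],
                             self.risk_counts[Group.CONTROL]], dtype=float))

    def sex_table(self) -> ContingencyTable:
        return ContingencyTable(
            row_labels=("asthma", "control"), col_labels=("male", "female"),
            counts=np.array(
                [(self.demographics[g].n_male, self.demographics[g].n_female)
                 for g in _GROUPS], dtype=float))


HAN = StudySummary(
    name="han",
    n_case=101,
    n_control=92,
    genotype_pct={
        "rs1042713": (("AA", "AG", "GG"), {
            Group.ASTHMA: (28.71, 59.41, 11.88),
            Group.CONTROL: (17.39, 52.17, 30.43),
        }),
        "rs2243250": (("TT", "TC", "CC"), {
            Group.ASTHMA: (70.30, 25.74, 3.96),
            Group.CONTROL: (50.00, 38.04, 11.96),
        }),
        "rs569108": (("AA", "AG", "GG"), {
            Group.ASTHMA: (67.33, 27.72, 4.95),
            Group.CONTROL: (76.09, 21.74, 2.17),
        }),
        "rs20541": (("AA", "AG", "GG"), {
            Group.ASTHMA: (11.88, 48.51, 39.61),
            Group.CONTROL: (31.52, 47.83, 20.65),
        }),
    },
    demographics={
        Group.ASTHMA: GroupDemographics(66, 35, SummaryStats(6.48, 2.38, 101)),
        Group.CONTROL: GroupDemographics(48, 44, SummaryStats(5.74, 3.70, 92)),
    },
    risk_counts={Group.ASTHMA: (45, 56), Group.CONTROL: (22, 70)},
)

KAZAK = StudySummary(
    name="kazak",
    n_case=80,
    n_control=93,
    genotype_pct={
        "rs1042713": (("AA", "AG", "GG"), {
            Group.ASTHMA: (21.25, 43.75, 35.00),
            Group.CONTROL: (17.20, 41.94, 40.86),
        }),
        "rs2243250": (("TT", "TC", "CC"), {
            Group.ASTHMA: (22.50, 55.00, 22.50),
            Group.CONTROL: (31.18, 51.61, 17.21),
        }),
        "rs569108": (("AA", "AG", "GG"), {
            Group.ASTHMA: (81.25, 16.25, 2.50),
            Group.CONTROL: (87.10, 11.83, 1.07),
        }),
        "rs20541": (("AA", "AG", "GG"), {
            Group.ASTHMA: (11.25, 43.75, 45.00),
            Group.CONTROL: (12.90, 53.76, 33.34),
        }),
    },
    demographics={
        Group.ASTHMA: GroupDemographics(48, 32, SummaryStats(4.89, 3.63, 80)),
        Group.CONTROL: GroupDemographics(55, 38, SummaryStats(4.98, 3.37, 93)),
    },
    risk_counts={Group.ASTHMA: (15, 65), Group.CONTROL: (16, 77)},
)

STUDIES = {"han": HAN, "kazak": KAZAK}
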