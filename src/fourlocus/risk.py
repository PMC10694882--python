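"""The four-locus asthma risk-genotype model.

A sample's *risk profile* records, per locus, whether it is homozygous for
the risk allele (ADRB2 AA, IL4 TT, FCER1B GG, IL13 GG). The model partitions
the 16 possible profiles into high- and low-risk classes.

The canonical fixed partition shipped here classifies as low risk: the
profile with no risk homozygotes (the reference), every single risk
homozygote, and the two pairs {ADRB2, FCER1B} and {IL13, FCER1B}; the
remaining four pairs, all four triples and the quadruple are high risk.

``derive_model`` reproduces the construction procedure on data: each
non-reference profile is compared with the reference in a 2x2
profile-by-group table and classed high iff p < alpha and OR > 1 (strict
inequalities; no multiple-testing correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .association import (ChiSquareResult, ContingencyTable, ORResult,
                          choose_test, odds_ratio_ci, pearson_chi2)
from .cohort import Cohort, Group, SampleRecord
from .errors import DerivationError, ValidationError
from .loci import ADRB2, FCER1B, IL4, IL13, PANEL


@dataclass(frozen=True)
class RiskProfile:
    """Risk-homozygosity flags, one per locus."""

    adrb2: bool
    il4: bool
    fcer1b: bool
    il13: bool

    @classmethod
    def from_flags(cls, flags: tuple[bool, bool, bool, bool]) -> "RiskProfile":
        return cls(*flags)

    @classmethod
    def from_bits(cls, bits: str) -> "RiskProfile":
        if len(bits) != 4 or set(bits) - {"0", "1"}:
            raise ValidationError(f"bad profile bitstring {bits!r}")
        return cls(*(b == "1" for b in bits))

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        """Flags in panel order (ADRB2, IL4, FCER1B, IL13)."""
        return (self.adrb2, self.il4, self.fcer1b, self.il13)

    @property
    def bits(self) -> str:
        return "".join("1" if f else "0" for f in self.flags)

    @property
    def n_risk_homozygotes(self) -> int:
        return sum(self.flags)

    @property
    def hom_genes(self) -> frozenset[str]:
        return frozenset(l.gene for l, f in zip(PANEL, self.flags) if f)

    def __str__(self) -> str:
        return "+".join(sorted(self.hom_genes)) or "reference"


ALL_PROFILES: tuple[RiskProfile, ...] = tuple(
    RiskProfile.from_bits(f"{i:04b}") for i in range(16)
)
REFERENCE_PROFILE = RiskProfile(False, False, False, False)

RiskClass = Literal["high", "low"]

#: Risk-homozygote pairs the fixed model nonetheless classes as low risk.
_LOW_RISK_PAIRS = (
    frozenset({ADRB2.gene, FCER1B.gene}),
    frozenset({IL13.gene, FCER1B.gene}),
)


def _fixed_class(profile: RiskProfile) -> RiskClass:
    k = profile.n_risk_homozygotes
    if k <= 1:
        return "low"
    if k == 2 and profile.hom_genes in _LOW_RISK_PAIRS:
        return "low"
    return "high"


@dataclass(frozen=True)
class ComboStats:
    """Per-profile comparison against the reference profile."""

    n_case: int
    n_control: int
    odds_ratio: Optional[float]
    p_value: Optional[float]
    method: Optional[str]


@dataclass(frozen=True)
class RiskModel:
    """Total mapping of all 16 risk profiles to high/low classes."""

    mapping: dict[RiskProfile, RiskClass]
    provenance: Literal["fixed", "derived"]
    combo_stats: dict[RiskProfile, ComboStats] = field(default_factory=dict)
    unobserved: frozenset[RiskProfile] = frozenset()

    def __post_init__(self) -> None:
        if set(self.mapping) != set(ALL_PROFILES):
            raise ValidationError("risk model must map all 16 profiles")
        if self.mapping[REFERENCE_PROFILE] != "low":
            raise ValidationError("the reference profile is always low risk")

    def classify(self, profile: RiskProfile) -> RiskClass:
        return self.mapping[profile]

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "provenance": self.provenance,
            "mapping": {p.bits: self.mapping[p] for p in ALL_PROFILES},
            "unobserved": sorted(p.bits for p in self.unobserved),
            "combo_stats": {
                p.bits: {
                    "n_case": s.n_case, "n_control": s.n_control,
                    "odds_ratio": s.odds_ratio, "p_value": s.p_value,
                    "method": s.method,
                }
                for p, s in sorted(self.combo_stats.items(),
                                   key=lambda kv: kv[0].bits)
            },
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        payload = json.loads(text)
        mapping = {RiskProfile.from_bits(b): c
                   for b, c in payload["mapping"].items()}
        stats = {
            RiskProfile.from_bits(b): ComboStats(
                n_case=s["n_case"], n_control=s["n_control"],
                odds_ratio=s["odds_ratio"], p_value=s["p_value"],
                method=s["method"])
            for b, s in payload.get("combo_stats", {}).items()
        }
        return cls(mapping=mapping, provenance=payload["provenance"],
                   combo_stats=stats,
                   unobserved=frozenset(RiskProfile.from_bits(b)
                                        for b in payload.get("unobserved", [])))


FIXED_MODEL = RiskModel(
    mapping={p: _fixed_class(p) for p in ALL_PROFILES},
    provenance="fixed",
)


def risk_profile(sample: SampleRecord) -> RiskProfile:
    """Extract the per-locus risk-homozygosity flags from a complete sample."""
    if not sample.is_complete:
        raise ValidationError(
            f"sample {sample.sample_id}: risk profile needs all four "
            "genotypes; at least one is missing"
        )
    return RiskProfile.from_flags(
        tuple(sample.genotype(l).is_risk_homozygote for l in PANEL)
    )


def classify_fixed(profile: RiskProfile) -> RiskClass:
    """Class under the canonical fixed partition (total over all 16 profiles)."""
    return FIXED_MODEL.classify(profile)


def _profile_counts(cohort: Cohort, group: Group) -> dict[RiskProfile, int]:
    counts = {p: 0 for p in ALL_PROFILES}
    for sample in cohort.group_samples(group):
        if sample.is_complete:
            counts[risk_profile(sample)] += 1
    return counts


def derive_model(cohort: Cohort, alpha: float = 0.05) -> RiskModel:
    """Re-derive the high/low partition from a two-group cohort.

    Each observed non-reference profile is compared with the reference in a
    2x2 (profile vs reference) x (asthma vs control) table; the test is
    Fisher exact when any expected count is below 5, else Pearson. A profile
    is high risk iff p < alpha and OR > 1 (both strict). Profiles observed in
    neither group inherit the fixed class and are flagged unobserved.
    """
    case_counts = _profile_counts(cohort, Group.ASTHMA)
    control_counts = _profile_counts(cohort, Group.CONTROL)
    ref_case = case_counts[REFERENCE_PROFILE]
    ref_control = control_counts[REFERENCE_PROFILE]
    if ref_case == 0 or ref_control == 0:
        raise DerivationError(
            "reference profile (no risk homozygotes) absent from "
            + ("both groups" if ref_case == ref_control == 0
               else "the asthma group" if ref_case == 0
               else "the control group")
        )
    mapping: dict[RiskProfile, RiskClass] = {REFERENCE_PROFILE: "low"}
    combo_stats: dict[RiskProfile, ComboStats] = {}
    unobserved: set[RiskProfile] = set()
    for profile in ALL_PROFILES:
        if profile == REFERENCE_PROFILE:
            continue
        a, c = case_counts[profile], control_counts[profile]
        if a + c == 0:
            mapping[profile] = _fixed_class(profile)
            unobserved.add(profile)
            continue
        table = ContingencyTable(
            row_labels=("asthma", "control"),
            col_labels=(str(profile), "reference"),
            counts=np.array([[a, ref_case], [c, ref_control]], dtype=float),
        )
        test = choose_test(table)
        # point OR; reference cells are positive, so only a or c can be zero
        odds = float("inf") if c == 0 else (a * ref_control) / (ref_case * c)
        mapping[profile] = ("high" if test.p_value < alpha and odds > 1
                            else "low")
        combo_stats[profile] = ComboStats(
            n_case=a, n_control=c,
            odds_ratio=None if odds == float("inf") else odds,
            p_value=test.p_value, method=test.method,
        )
    return RiskModel(mapping=mapping, provenance="derived",
                     combo_stats=combo_stats, unobserved=frozenset(unobserved))


def risk_class_table(cohort: Cohort, model: RiskModel) -> ContingencyTable:
    """2x2 table of classifiable samples per (group, risk class)."""
    counts = np.zeros((2, 2))
    for i, group in enumerate((Group.ASTHMA, Group.CONTROL)):
        for sample in cohort.group_samples(group):
            if not sample.is_complete:
                continue
            j = 0 if model.classify(risk_profile(sample)) == "high" else 1
            counts[i, j] += 1
    return ContingencyTable(row_labels=("asthma", "control"),
                            col_labels=("high", "low"), counts=counts)


def risk_distribution_test(
    cohort: Cohort, model: RiskModel
) -> tuple[ContingencyTable, ChiSquareResult, ORResult]:
    """Compare the high/low-risk distribution between groups.

    Returns the 2x2 table, the Pearson chi-square result and the odds ratio
    (high risk as exposure) with its Woolf 95% CI.
    """
    table = risk_class_table(cohort, model)
    return table, pearson_chi2(table), odds_ratio_ci(table)
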