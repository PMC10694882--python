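"""Per-sample data model for two-group four-locus cohorts."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import ValidationError
from .loci import PANEL, Genotype, Locus


class Group(enum.Enum):
    ASTHMA = "asthma"
    CONTROL = "control"

    @classmethod
    def parse(cls, label: str) -> "Group":
        """Case-insensitive group label: asthma/case vs control/healthy."""
        token = label.strip().lower()
        if token in {"asthma", "case"}:
            return cls.ASTHMA
        if token in {"control", "healthy"}:
            return cls.CONTROL
        raise ValidationError(f"unknown group label {label!r}")


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, label: str) -> "Sex":
        token = label.strip().lower()
        if token in {"male", "m", "boy"}:
            return cls.MALE
        if token in {"female", "f", "girl"}:
            return cls.FEMALE
        if token in {"", "na", "unknown", "."}:
            return cls.UNKNOWN
        raise ValidationError(f"unknown sex label {label!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One child: id, group, demographics and the four genotype calls."""

    sample_id: str
    group: Group
    sex: Sex = Sex.UNKNOWN
    age_years: Optional[float] = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {locus.rs_id for locus in PANEL}
        if set(self.genotypes) != expected:
            raise ValidationError(
                f"sample {self.sample_id}: genotypes must cover exactly "
                f"{sorted(expected)}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(f"sample {self.sample_id}: negative age")

    def genotype(self, locus: Locus) -> Genotype:
        return self.genotypes[locus.rs_id]

    @property
    def is_complete(self) -> bool:
        """True iff all four genotype calls are non-missing."""
        return not any(g.is_missing for g in self.genotypes.values())


@dataclass
class Cohort:
    """A named collection of samples spanning the two study groups."""

    name: str
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)

    def group_samples(self, group: Group) -> list[SampleRecord]:
        return [s for s in self.samples if s.group == group]

    def group_size(self, group: Group) -> int:
        return sum(1 for s in self.samples if s.group == group)

    def extend(self, records: Iterable[SampleRecord]) -> None:
        for r in records:
            self.samples.append(r)
        # re-run duplicate check
        self.__post_init__()
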