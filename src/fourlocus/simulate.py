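"""Seeded simulator for two-group four-locus genotype cohorts.

Stands in for unpublished per-child data: each group is described by a
per-locus genotype distribution (risk-homozygote, heterozygote, other
homozygote), a sex probability and a truncated-normal age model (ages are
clipped to [0, 14], the cohorts' inclusion window, by rejection sampling).

Within a group, loci are sampled independently by default — only marginal
genotype distributions are published, so no linkage structure is assumed.
``plant_risk_effect`` is the one mechanism that induces cross-locus
structure: it reweights the case group's joint distribution over the 16
risk-homozygosity profiles so chosen profiles' odds against the
no-risk-homozygote reference are multiplied by a target odds ratio, leaving
the control group untouched. Genotypes are drawn from the genotype
distribution directly (not from allele frequencies under Hardy-Weinberg), so
simulated marginals track the published tables even where those deviate from
HWE; ``hwe_mode`` opts in to HWE sampling from the implied allele frequency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .cohort import Cohort, Group, SampleRecord, Sex
from .errors import SpecError
from .freq import GenotypeCounts
from .loci import LOCI_BY_RS, PANEL, Genotype, Locus
from .risk import ALL_PROFILES, REFERENCE_PROFILE, RiskProfile

AGE_RANGE = (0.0, 14.0)


def _check_probs(probs: Sequence[float], what: str, k: int) -> tuple[float, ...]:
    p = tuple(float(x) for x in probs)
    if len(p) != k or min(p) < 0 or abs(sum(p) - 1.0) > 1e-9:
        raise SpecError(f"{what}: need {k} non-negative probabilities summing to 1")
    return p


@dataclass(frozen=True)
class LocusGroupSpec:
    """Genotype distribution at one locus within one group.

    ``genotype_probs`` is (risk homozygote, heterozygote, other homozygote).
    """

    locus: Locus
    genotype_probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genotype_probs",
            _check_probs(self.genotype_probs, self.locus.rs_id, 3))

    @property
    def risk_hom_prob(self) -> float:
        return self.genotype_probs[0]


@dataclass(frozen=True)
class GroupSpec:
    """Sample size, genotype model and demographics for one group."""

    n: int
    loci: Mapping[str, LocusGroupSpec]
    male_prob: float = 0.5
    age_mean: float = 6.0
    age_sd: float = 3.0
    #: optional joint distribution over the 16 risk profiles (bits -> prob);
    #: set by plant_risk_effect, None means independent loci
    profile_weights: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SpecError("group sample size must be positive")
        if set(self.loci) != set(LOCI_BY_RS):
            raise SpecError("group spec must cover exactly the four panel loci")
        if not 0 <= self.male_prob <= 1:
            raise SpecError("male_prob must lie in [0, 1]")
        if self.age_sd <= 0:
            raise SpecError("age_sd must be positive")
        if self.profile_weights is not None:
            w = dict(self.profile_weights)
            _check_probs([w.get(p.bits, 0.0) for p in ALL_PROFILES],
                         "profile_weights", 16)

    def independent_profile_weights(self) -> dict[str, float]:
        """Joint profile distribution implied by independent loci."""
        out = {}
        for profile in ALL_PROFILES:
            w = 1.0
            for locus, flag in zip(PANEL, profile.flags):
                p = self.loci[locus.rs_id].risk_hom_prob
                w *= p if flag else 1.0 - p
            out[profile.bits] = w
        return out


@dataclass(frozen=True)
class SimulationSpec:
    """Full two-group cohort simulation specification."""

    cohort_name: str
    case: GroupSpec
    control: GroupSpec
    seed: int = 0
    hwe_mode: bool = False

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def group(g: GroupSpec) -> dict:
            return {
                "n": g.n,
                "male_prob": g.male_prob,
                "age_mean": g.age_mean,
                "age_sd": g.age_sd,
                "genotype_probs": {rs: list(s.genotype_probs)
                                   for rs, s in sorted(g.loci.items())},
                "profile_weights": (None if g.profile_weights is None
                                    else dict(sorted(g.profile_weights.items()))),
            }
        return {"cohort_name": self.cohort_name, "seed": self.seed,
                "hwe_mode": self.hwe_mode,
                "case": group(self.case), "control": group(self.control)}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationSpec":
        def group(d: Mapping) -> GroupSpec:
            try:
                loci = {rs: LocusGroupSpec(LOCI_BY_RS[rs], tuple(probs))
                        for rs, probs in d["genotype_probs"].items()}
            except KeyError as exc:
                raise SpecError(f"unknown or missing locus in spec: {exc}") from exc
            return GroupSpec(n=int(d["n"]), loci=loci,
                             male_prob=float(d.get("male_prob", 0.5)),
                             age_mean=float(d.get("age_mean", 6.0)),
                             age_sd=float(d.get("age_sd", 3.0)),
                             profile_weights=d.get("profile_weights"))
        try:
            return cls(cohort_name=str(payload["cohort_name"]),
                       seed=int(payload.get("seed", 0)),
                       hwe_mode=bool(payload.get("hwe_mode", False)),
                       case=group(payload["case"]),
                       control=group(payload["control"]))
        except KeyError as exc:
            raise SpecError(f"simulation spec missing key {exc}") from exc

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=True)
                if path.suffix in {".yaml", ".yml"}
                else json.dumps(self.to_dict(), indent=2, sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SimulationSpec":
        path = Path(path)
        if not path.exists():
            raise SpecError(f"spec file not found: {path}")
        text = path.read_text()
        payload = (yaml.safe_load(text) if path.suffix in {".yaml", ".yml"}
                   else json.loads(text))
        return cls.from_dict(payload)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float, hi: float) -> np.ndarray:
    """Rejection-sampled normal restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def _genotype_from_code(locus: Locus, code: int) -> Genotype:
    """0 = risk homozygote, 1 = heterozygote, 2 = other homozygote."""
    if code == 0:
        return Genotype(locus, locus.risk_homozygote)
    if code == 1:
        order = {locus.allele_1: 0, locus.allele_2: 1}
        pair = tuple(sorted((locus.risk_allele, locus.nonrisk_allele),
                            key=order.__getitem__))
        return Genotype(locus, pair)  # type: ignore[arg-type]
    return Genotype(locus, (locus.nonrisk_allele, locus.nonrisk_allele))


def _sample_group(rng: np.random.Generator, spec: GroupSpec, group: Group,
                  name_prefix: str, hwe_mode: bool) -> list[SampleRecord]:
    n = spec.n
    codes: dict[str, np.ndarray] = {}
    if spec.profile_weights is None:
        for locus in PANEL:
            probs = np.asarray(spec.loci[locus.rs_id].genotype_probs)
            if hwe_mode:
                p = probs[0] + probs[1] / 2.0  # implied risk-allele frequency
                probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
            codes[locus.rs_id] = rng.choice(3, size=n, p=probs)
    else:
        weights = np.array([spec.profile_weights.get(p.bits, 0.0)
                            for p in ALL_PROFILES])
        profile_idx = rng.choice(16, size=n, p=weights)
        flags = np.array([p.flags for p in ALL_PROFILES], dtype=bool)
        for j, locus in enumerate(PANEL):
            probs = spec.loci[locus.rs_id].genotype_probs
            cond = probs[1] + probs[2]
            locus_codes = np.zeros(n, dtype=int)
            non_hom = ~flags[profile_idx, j]
            k = int(non_hom.sum())
            if k:
                if cond <= 0:
                    raise SpecError(
                        f"{locus.rs_id}: profile weights allow non-homozygous "
                        "profiles but the genotype model has no heterozygote "
                        "or other-homozygote mass")
                p_het = probs[1] / cond
                locus_codes[non_hom] = np.where(rng.random(k) < p_het, 1, 2)
            codes[locus.rs_id] = locus_codes
    sexes = np.where(rng.random(n) < spec.male_prob, Sex.MALE.value,
                     Sex.FEMALE.value)
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, n, *AGE_RANGE)
    records = []
    for i in range(n):
        genotypes = {locus.rs_id: _genotype_from_code(locus,
                                                      int(codes[locus.rs_id][i]))
                     for locus in PANEL}
        records.append(SampleRecord(
            sample_id=f"{name_prefix}-{group.value}-{i + 1:04d}",
            group=group, sex=Sex(sexes[i]),
            age_years=round(float(ages[i]), 2), genotypes=genotypes))
    return records


def simulate_cohort(spec: SimulationSpec,
                    seed: Optional[int] = None) -> Cohort:
    """Draw a cohort from a spec; fully reproducible given (spec, seed).

    ``seed`` overrides the seed stored in the spec.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    samples = _sample_group(rng, spec.case, Group.ASTHMA, spec.cohort_name,
                            spec.hwe_mode)
    samples += _sample_group(rng, spec.control, Group.CONTROL,
                             spec.cohort_name, spec.hwe_mode)
    return Cohort(name=spec.cohort_name, samples=samples)


def spec_from_counts(counts: Mapping[Group, Mapping[str, GenotypeCounts]],
                     demographics: Optional[Mapping[Group, Mapping[str, float]]]
                     = None,
                     cohort_name: str = "cohort",
                     seed: int = 0) -> SimulationSpec:
    """Build a simulation spec whose genotype probabilities are normalized
    observed (or reconstructed) counts.

    ``demographics`` optionally maps each group to keys ``male_prob``,
    ``age_mean``, ``age_sd``; group sizes come from the counts' totals.
    """
    groups = {}
    for group in (Group.ASTHMA, Group.CONTROL):
        per_locus = counts[group]
        if set(per_locus) != set(LOCI_BY_RS):
            raise SpecError("counts must cover exactly the four panel loci")
        totals = {rs: c.total for rs, c in per_locus.items()}
        n = max(totals.values())
        if n == 0:
            raise SpecError(f"{group.value}: zero genotype totals")
        loci = {}
        for rs, c in per_locus.items():
            if c.total == 0:
                raise SpecError(f"{group.value}/{rs}: zero genotype total")
            loci[rs] = LocusGroupSpec(
                c.locus, tuple(x / c.total for x in c.as_tuple()))
        demo = dict((demographics or {}).get(group, {}))
        groups[group] = GroupSpec(n=n, loci=loci, **demo)
    return SimulationSpec(cohort_name=cohort_name, seed=seed,
                          case=groups[Group.ASTHMA],
                          control=groups[Group.CONTROL])


def plant_risk_effect(spec: SimulationSpec,
                      target_combinations: Iterable[RiskProfile],
                      odds_ratio: float) -> SimulationSpec:
    """Reweight the case group's joint risk-profile distribution.

    Each target profile's odds against the reference profile are multiplied
    by ``odds_ratio``; the control group is unchanged; the joint distribution
    is renormalized. Targeting the reference profile is an error.
    """
    targets = set(target_combinations)
    if odds_ratio <= 0:
        raise SpecError("odds_ratio must be positive")
    if REFERENCE_PROFILE in targets:
        raise SpecError("cannot plant an effect on the reference profile")
    base = (dict(spec.case.profile_weights)
            if spec.case.profile_weights is not None
            else spec.case.independent_profile_weights())
    target_bits = {p.bits for p in targets}
    weights = {bits: w * odds_ratio if bits in target_bits else w
               for bits, w in base.items()}
    total = sum(weights.values())
    weights = {bits: w / total for bits, w in weights.items()}
    case = GroupSpec(n=spec.case.n, loci=spec.case.loci,
                     male_prob=spec.case.male_prob,
                     age_mean=spec.case.age_mean, age_sd=spec.case.age_sd,
                     profile_weights=weights)
    return SimulationSpec(cohort_name=spec.cohort_name, case=case,
                          control=spec.control, seed=spec.seed,
                          hwe_mode=spec.hwe_mode)


def cohort_from_counts(name: str,
                       counts: Mapping[Group, Mapping[str, GenotypeCounts]]
                       ) -> Cohort:
    """Deterministic cohort realizing given per-locus genotype counts exactly.

    Genotypes are laid out locus-wise in a fixed order, so per-locus counts
    (and everything derived from them) match the input exactly; the joint
    cross-locus structure is artificial and not meaningful for risk-profile
    analyses.
    """
    samples: list[SampleRecord] = []
    for group in (Group.ASTHMA, Group.CONTROL):
        per_locus = counts[group]
        totals = {c.total for c in per_locus.values()}
        if len(totals) != 1:
            raise SpecError(f"{group.value}: locus totals disagree: {totals}")
        n = totals.pop()
        columns = {}
        for locus in PANEL:
            c = per_locus[locus.rs_id]
            codes = [0] * c.n_aa + [1] * c.n_ab + [2] * c.n_bb
            columns[locus.rs_id] = [_genotype_from_code(locus, k)
                                    for k in codes]
        for i in range(n):
            samples.append(SampleRecord(
                sample_id=f"{name}-{group.value}-{i + 1:04d}", group=group,
                genotypes={rs: columns[rs][i] for rs in columns}))
    return Cohort(name=name, samples=samples)
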