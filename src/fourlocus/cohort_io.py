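"""Readers and writers for genotype cohorts, plus count reconstruction.

Tabular format (TSV/CSV): header row with columns ``sample_id, group, sex,
age, rs1042713, rs2243250, rs569108, rs20541``; genotypes as two-character
strings in either allele order; missing calls as "NA" (or any token in
:data:`fourlocus.loci.MISSING_TOKENS`).

VCF: standard VCF 4.x parsed with pysam, sites matched by the ID column
against the four rs-IDs; sample-to-group assignment from a two-column sidecar
TSV (sample_id, group). GT indices are decoded against REF/ALT and the
phasing separator is ignored — calls here are unordered pairs.

``reconstruct_counts`` turns a published percentage row plus a group size
back into integer genotype counts (the study prints percentages only).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort, Group, SampleRecord, Sex
from .errors import CountConsistencyWarning, FormatError, ValidationError
from .loci import LOCI_BY_RS, PANEL, Genotype, normalize_genotype

PathLike = Union[str, Path]

_REQUIRED_COLUMNS = ["sample_id", "group", "sex", "age"] + [l.rs_id for l in PANEL]


def _parse_age(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    token = str(value).strip()
    if token.lower() in {"", "na", "nan", "."}:
        return None
    return float(token)


def read_cohort(path: PathLike, format: str = "tsv",
                group_map: Optional[PathLike] = None,
                name: Optional[str] = None) -> Cohort:
    """Read a cohort from ``tsv``, ``csv`` or ``vcf``.

    For VCF a ``group_map`` sidecar (two-column TSV: sample_id, group) is
    required, since VCF carries no phenotype labels.
    """
    path = Path(path)
    cohort_name = name if name is not None else path.stem
    if format in {"tsv", "csv"}:
        return _read_table(path, sep="\t" if format == "tsv" else ",",
                           name=cohort_name)
    if format == "vcf":
        if group_map is None:
            raise FormatError("VCF input requires a sample-to-group sidecar map")
        return _read_vcf(path, Path(group_map), name=cohort_name)
    raise FormatError(f"unknown cohort format {format!r}")


def _read_table(path: Path, sep: str, name: str) -> Cohort:
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    records = []
    for _, row in frame.iterrows():
        sid = row["sample_id"].strip()
        genotypes = {
            locus.rs_id: normalize_genotype(row[locus.rs_id], locus, context=sid)
            for locus in PANEL
        }
        records.append(SampleRecord(
            sample_id=sid,
            group=Group.parse(row["group"]),
            sex=Sex.parse(row["sex"]),
            age_years=_parse_age(row["age"]),
            genotypes=genotypes,
        ))
    return Cohort(name=name, samples=records)


def write_cohort(cohort: Cohort, path: PathLike, format: str = "tsv") -> None:
    """Write a cohort as TSV or CSV (lossless round-trip with read_cohort)."""
    if format not in {"tsv", "csv"}:
        raise FormatError(f"unsupported output format {format!r}")
    sep = "\t" if format == "tsv" else ","
    rows = []
    for s in cohort:
        row = {
            "sample_id": s.sample_id,
            "group": s.group.value,
            "sex": s.sex.value,
            "age": "" if s.age_years is None else f"{s.age_years:g}",
        }
        for locus in PANEL:
            row[locus.rs_id] = str(s.genotype(locus))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)
    frame.to_csv(path, sep=sep, index=False)


def _read_group_map(path: Path) -> dict[str, Group]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: group map needs columns sample_id, group")
    id_col, grp_col = frame.columns[:2]
    return {row[id_col].strip(): Group.parse(row[grp_col])
            for _, row in frame.iterrows()}


def _read_vcf(path: Path, group_map_path: Path, name: str) -> Cohort:
    import pysam

    groups = _read_group_map(group_map_path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    sample_names = list(vcf.header.samples)
    calls: dict[str, dict[str, Genotype]] = {s: {} for s in sample_names}
    for rec in vcf:
        if rec.id not in LOCI_BY_RS:
            continue
        locus = LOCI_BY_RS[rec.id]
        site_alleles = (rec.ref,) + tuple(rec.alts or ())
        for allele in site_alleles:
            if allele not in locus.alleles:
                raise FormatError(
                    f"{path}: site {rec.id} allele {allele!r} not in "
                    f"{locus.allele_1}/{locus.allele_2}"
                )
        for sname in sample_names:
            gt = rec.samples[sname].get("GT")
            if gt is None or any(i is None for i in gt):
                calls[sname][locus.rs_id] = Genotype(locus, None)
                continue
            raw = "".join(site_alleles[i] for i in gt)
            calls[sname][locus.rs_id] = normalize_genotype(raw, locus,
                                                           context=sname)
    records = []
    for sname in sample_names:
        if sname not in groups:
            raise ValidationError(f"sample {sname!r} absent from group map")
        genotypes = {
            locus.rs_id: calls[sname].get(locus.rs_id, Genotype(locus, None))
            for locus in PANEL
        }
        records.append(SampleRecord(sample_id=sname, group=groups[sname],
                                    genotypes=genotypes))
    return Cohort(name=name, samples=records)


def reconstruct_counts(percentages: Sequence[float], n: int) -> np.ndarray:
    """Integer counts from a published percentage row and a group size.

    Each count is ``round(pct/100 * n)`` to the nearest integer, half away
    from zero. If the rounded counts do not sum to ``n`` a
    :class:`CountConsistencyWarning` is recorded (published tables contain
    typos; reconstruction must not halt on them).
    """
    pct = np.asarray(percentages, dtype=float)
    if np.any(pct < 0):
        raise ValidationError("percentages must be non-negative")
    if n <= 0:
        raise ValidationError("group size must be positive")
    counts = np.floor(pct * n / 100.0 + 0.5).astype(int)
    if counts.sum() != n:
        warnings.warn(
            f"reconstructed counts {counts.tolist()} sum to {counts.sum()}, "
            f"not the stated group size {n}",
            CountConsistencyWarning,
            stacklevel=2,
        )
    return counts
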