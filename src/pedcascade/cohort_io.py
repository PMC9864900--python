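"""Readers/writers for the cohort formats and the joined Cohort container.

The pipeline consumes a multi-sample VCF (genotypes), a 6-column PED file
(pedigree structure and affection status) and a TSV annotation table
(population allele frequencies, in-silico scores, cardiac expression).
This module parses each into typed records and joins them into a single
:class:`Cohort` keyed by ``chrom:pos:ref:alt``.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention); no liftover.
* Genotypes are unphased: ``0/1`` and ``1/0`` are both HET; ``./.`` is MISSING.
* Missing annotation cells become ``None``, never ``0`` — downstream filters
  decide per-operation whether a missing value passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from cyvcf2 import VCF

PUBLIC_DATABASES = ("gnomAD", "1000Genomes", "ExAC", "EVS")


class FormatError(ValueError):
    """Input file violates the expected format."""


class LookupError_(KeyError):
    """A requested sample/record is absent."""


class Genotype(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class AggregatePrediction(str, Enum):
    BENIGN = "BENIGN"
    NON_BENIGN = "NON_BENIGN"


@dataclass
class Variant:
    """A single ALT allele at a locus with per-sample genotype classes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class AnnotationRecord:
    """Per-variant annotation: frequencies, prediction scores, expression.

    ``None`` means the value was not reported — distinct from zero.
    ``aggregate_score`` plays the role of a 0–1 combined damage score (the
    Omicia-style score); ``aggregate_prediction`` the Franklin-style verdict.
    """

    key: str
    af_public: dict[str, float | None] = field(default_factory=dict)
    af_internal: float | None = None
    in_internal_db: bool = False
    present_in_population_archives: bool = False
    sift: float | None = None
    cadd: float | None = None
    aggregate_score: float | None = None
    aggregate_prediction: AggregatePrediction | None = None
    heart_expression: float | None = None
    clinical_mismatch: bool = False
    known_phenotype_gene: bool = False

    def __post_init__(self) -> None:
        for db, af in self.af_public.items():
            if af is not None and not 0.0 <= af <= 1.0:
                raise FormatError(f"{self.key}: {db} AF {af} outside [0, 1]")
        if self.af_internal is not None and not 0.0 <= self.af_internal <= 1.0:
            raise FormatError(f"{self.key}: internal AF {self.af_internal} outside [0, 1]")
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise FormatError(f"{self.key}: SIFT {self.sift} outside [0, 1]")


@dataclass
class PedMember:
    id: str
    sex: int  # 1 male, 2 female, 0 unknown
    father_id: str | None
    mother_id: str | None
    affected: bool


@dataclass
class Pedigree:
    members: list[PedMember]
    consanguinity: str = ""

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.affected]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.id for m in self.members if not m.affected]

    def member(self, member_id: str) -> PedMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise LookupError_(f"no pedigree member {member_id!r}")

    def parents_of(self, member_id: str) -> tuple[str | None, str | None]:
        m = self.member(member_id)
        return m.father_id, m.mother_id


@dataclass
class Cohort:
    """Variants joined with annotations under one pedigree."""

    variants: list[Variant]
    annotations: dict[str, AnnotationRecord]
    pedigree: Pedigree

    def annotation(self, variant: Variant) -> AnnotationRecord:
        return self.annotations[variant.key]

    def variant(self, key: str) -> Variant:
        for v in self.variants:
            if v.key == key:
                return v
        raise LookupError_(f"no variant {key!r} in cohort")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_gt(allele_a: int, allele_b: int, alt_index: int) -> Genotype:
    """Map a diploid unphased genotype to a class relative to one ALT allele.

    ``alt_index`` is 1-based within the record's ALT list. Alleles other than
    this ALT count as reference for the decomposed variant.
    """
    if allele_a < 0 or allele_b < 0:
        return Genotype.MISSING
    n_alt = (allele_a == alt_index) + (allele_b == alt_index)
    if n_alt == 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def read_vcf(path: str | Path, sample_ids: Iterable[str] | None = None,
             gene_info_field: str = "GENE") -> list[Variant]:
    """Read a VCF 4.x into decomposed :class:`Variant` records.

    One Variant is emitted per ALT allele per record (multi-allelic records
    are decomposed, sharing the position). Genotypes are taken from the GT
    FORMAT field; the gene symbol, if present, from the ``GENE`` INFO key.
    """
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if not header_samples:
        raise FormatError(f"{path}: VCF has no sample columns (GT required)")
    if sample_ids is None:
        sample_ids = header_samples
    else:
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in header_samples]
        if missing:
            raise LookupError_(f"{path}: samples not in VCF header: {missing}")
    col = {s: header_samples.index(s) for s in sample_ids}

    out: list[Variant] = []
    for rec in vcf:
        if "GT" not in (rec.FORMAT or ""):
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GT")
        gts = rec.genotypes  # [allele_a, allele_b, phased] per sample
        gene = rec.INFO.get(gene_info_field) or ""
        for alt_i, alt in enumerate(rec.ALT, start=1):
            genotypes = {
                s: _classify_gt(gts[i][0], gts[i][1], alt_i)
                for s, i in col.items()
            }
            out.append(Variant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                               alt=alt, gene=gene, genotypes=genotypes))
    return out


_GT_CODE = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(path: str | Path, variants: list[Variant], sample_ids: list[str]) -> None:
    """Write decomposed variants back out as a minimal bi-allelic VCF 4.2.

    Deterministic plain-text emission: identical input yields byte-identical
    output (needed for seeded-generator reproducibility checks).
    """
    contigs = list(dict.fromkeys(v.chrom for v in variants))
    lines = ["##fileformat=VCFv4.2",
             *[f"##contig=<ID={c}>" for c in contigs],
             '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(sample_ids)]
    for v in variants:
        info = f"GENE={v.gene}" if v.gene else "."
        gts = "\t".join(_GT_CODE[v.genotypes.get(s, Genotype.MISSING)]
                        for s in sample_ids)
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (fam, id, father, mother, sex, phenotype).

    Phenotype 2 means affected. '0' parent ids mean founder. A parent id
    that is neither '0' nor a listed member is a structure error.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
        rows.append(fields[:6])
    if not rows:
        raise FormatError(f"{path}: empty PED file")

    ids = {r[1] for r in rows}
    members = []
    for _fam, iid, fid, mid, sex, pheno in rows:
        for parent in (fid, mid):
            if parent != "0" and parent not in ids:
                raise FormatError(f"{path}: member {iid} lists unknown parent {parent!r}")
        members.append(PedMember(
            id=iid,
            sex=int(sex),
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            affected=(pheno == "2"),
        ))
    return Pedigree(members=members)


def write_ped(path: str | Path, pedigree: Pedigree, family_id: str = "FAM1") -> None:
    lines = []
    for m in pedigree.members:
        lines.append("\t".join([
            family_id, m.id, m.father_id or "0", m.mother_id or "0",
            str(m.sex), "2" if m.affected else "1",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

_ANN_COLUMNS = [
    "key", "gene", "af_gnomAD", "af_1000Genomes", "af_ExAC", "af_EVS",
    "af_internal", "in_internal_db", "in_population_archives",
    "sift", "cadd", "aggregate_score", "aggregate_prediction",
    "heart_expression", "clinical_mismatch", "known_phenotype_gene",
]


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def _as_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in {"1", "true", "yes"}


def read_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read the TSV annotation table into records keyed by variant key.

    Empty cells are missing values (``None``), never zero; frequencies
    outside [0, 1] raise a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("key",) if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: annotation table lacks columns {missing_cols}")
    records: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        pred = row.get("aggregate_prediction", "")
        rec = AnnotationRecord(
            key=row["key"],
            af_public={db: _opt_float(row.get(f"af_{db}", "")) for db in PUBLIC_DATABASES},
            af_internal=_opt_float(row.get("af_internal", "")),
            in_internal_db=_as_bool(row.get("in_internal_db", "")),
            present_in_population_archives=_as_bool(row.get("in_population_archives", "")),
            sift=_opt_float(row.get("sift", "")),
            cadd=_opt_float(row.get("cadd", "")),
            aggregate_score=_opt_float(row.get("aggregate_score", "")),
            aggregate_prediction=AggregatePrediction(pred) if pred else None,
            heart_expression=_opt_float(row.get("heart_expression", "")),
            clinical_mismatch=_as_bool(row.get("clinical_mismatch", "")),
            known_phenotype_gene=_as_bool(row.get("known_phenotype_gene", "")),
        )
        records[rec.key] = rec
    return records


def write_annotations(path: str | Path,
                      annotations: dict[str, AnnotationRecord],
                      genes: dict[str, str] | None = None) -> None:
    def fmt(x) -> str:
        if x is None:
            return ""
        if isinstance(x, bool):
            return "true" if x else "false"
        if isinstance(x, AggregatePrediction):
            return x.value
        return repr(x) if isinstance(x, float) else str(x)

    lines = ["\t".join(_ANN_COLUMNS)]
    for key, a in annotations.items():
        row = [key, (genes or {}).get(key, "")]
        row += [fmt(a.af_public.get(db)) for db in PUBLIC_DATABASES]
        row += [fmt(a.af_internal), fmt(a.in_internal_db),
                fmt(a.present_in_population_archives), fmt(a.sift), fmt(a.cadd),
                fmt(a.aggregate_score), fmt(a.aggregate_prediction),
                fmt(a.heart_expression), fmt(a.clinical_mismatch),
                fmt(a.known_phenotype_gene)]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Join
# ---------------------------------------------------------------------------

def build_cohort(variants: list[Variant],
                 annotations: dict[str, AnnotationRecord],
                 pedigree: Pedigree) -> Cohort:
    """Join genotypes with annotations; every variant must have a record."""
    keys = [v.key for v in variants]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"duplicate variant keys: {dupes}")
    orphans = [k for k in keys if k not in annotations]
    if orphans:
        raise FormatError(f"variants without annotation records: {orphans}")
    for v in variants:
        for member_id in pedigree.ids:
            v.genotypes.setdefault(member_id, Genotype.MISSING)
    return Cohort(variants=variants, annotations=annotations, pedigree=pedigree)
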