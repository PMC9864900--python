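"""Pedigree segregation tests, ACMG-style evidence combination, the
zero-observation carrier-frequency bound, and cDNA-to-protein consequence
mapping — the adjudication steps that turn cascade survivors into a verdict.

Segregation models
------------------
* AR — autosomal recessive under homozygosity by descent: the affected
  proband is homozygous for the alternate allele, both parents are obligate
  heterozygous carriers, and no unaffected member is homozygous.
* DE_NOVO — the proband carries the allele while both parents are
  homozygous reference.
* AD_NEGATION — a putative dominant variant is negated once enough healthy
  relatives are shown to carry it (default: four).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .cohort_io import Genotype, Pedigree, Variant


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

@dataclass
class SegregationModel:
    mode: str  # AR, AD_NEGATION or DE_NOVO
    min_healthy_carriers_to_negate: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("AR", "AD_NEGATION", "DE_NOVO"):
            raise ValidationError(f"unknown segregation mode {self.mode!r}")
        if self.min_healthy_carriers_to_negate < 1:
            raise ValidationError("min_healthy_carriers_to_negate must be >= 1")


def segregation_consistent(variant: Variant, pedigree: Pedigree,
                           model: SegregationModel,
                           ) -> tuple[bool, dict[str, str]]:
    """Test a variant's genotypes against a segregation model.

    Returns (consistent, per-member verdicts). Members with MISSING
    genotypes are skipped and marked "skipped_missing" — except the proband,
    whose genotype is required. For AD_NEGATION, ``consistent`` is True when
    the negation FIRES (enough healthy carriers observed).
    """
    affected = pedigree.affected_ids
    if len(affected) != 1:
        raise ValidationError(f"expected exactly one affected member, found {affected}")
    proband = affected[0]
    g = variant.genotypes
    if g.get(proband, Genotype.MISSING) == Genotype.MISSING:
        raise ValidationError(f"proband {proband} genotype missing for {variant.key}")

    verdicts: dict[str, str] = {}
    for m in pedigree.members:
        if g.get(m.id, Genotype.MISSING) == Genotype.MISSING:
            verdicts[m.id] = "skipped_missing"

    if model.mode == "AR":
        ok = True
        if g[proband] != Genotype.HOM_ALT:
            verdicts[proband] = "proband_not_homozygous"
            ok = False
        else:
            verdicts[proband] = "homozygous_affected"
        father, mother = pedigree.parents_of(proband)
        for parent in (father, mother):
            if parent is None:
                continue
            gt = g.get(parent, Genotype.MISSING)
            if gt == Genotype.MISSING:
                continue  # already marked skipped
            if gt != Genotype.HET:
                verdicts[parent] = "parent_not_carrier"
                ok = False
            else:
                verdicts[parent] = "obligate_carrier"
        for member_id in pedigree.unaffected_ids:
            gt = g.get(member_id, Genotype.MISSING)
            if gt == Genotype.MISSING:
                continue
            if gt == Genotype.HOM_ALT:
                verdicts[member_id] = "unaffected_homozygous"
                ok = False
            else:
                verdicts.setdefault(member_id, "consistent")
        return ok, verdicts

    if model.mode == "DE_NOVO":
        carries = g[proband] in (Genotype.HET, Genotype.HOM_ALT)
        verdicts[proband] = "carrier" if carries else "non_carrier"
        ok = carries
        father, mother = pedigree.parents_of(proband)
        for parent in (father, mother):
            if parent is None:
                ok = False
                continue
            gt = g.get(parent, Genotype.MISSING)
            if gt == Genotype.MISSING:
                ok = False
                continue
            if gt == Genotype.HOM_REF:
                verdicts[parent] = "non_carrier"
            else:
                verdicts[parent] = "carrier_parent"
                ok = False
        return ok, verdicts

    # AD_NEGATION
    healthy_carriers = 0
    for member_id in pedigree.unaffected_ids:
        gt = g.get(member_id, Genotype.MISSING)
        if gt in (Genotype.HET, Genotype.HOM_ALT):
            verdicts[member_id] = "healthy_carrier"
            healthy_carriers += 1
        elif gt == Genotype.HOM_REF:
            verdicts[member_id] = "non_carrier"
    negated = healthy_carriers >= model.min_healthy_carriers_to_negate
    verdicts[proband] = "negated" if negated else "not_negated"
    return negated, verdicts


# ---------------------------------------------------------------------------
# Carrier-frequency bound
# ---------------------------------------------------------------------------

def carrier_frequency_bound(cohort_sizes: list[int]) -> tuple[int, float]:
    """Zero-observation upper bound on allele frequency.

    An allele never seen across surveyed cohorts totalling N individuals has
    frequency below 1 in 2N chromosomes. Returns (chromosome count, bound).
    """
    if any(n < 0 for n in cohort_sizes):
        raise ValidationError("cohort sizes must be >= 0")
    total = sum(cohort_sizes)
    if total == 0:
        raise ValidationError("at least one cohort must be non-empty")
    chromosomes = 2 * total
    return chromosomes, 1.0 / chromosomes


# ---------------------------------------------------------------------------
# Coding consequence
# ---------------------------------------------------------------------------

@dataclass
class CodingChange:
    """A cDNA substitution, e.g. c.1532G>A."""

    cds_position: int  # 1-based within the CDS
    ref_base: str
    alt_base: str
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValidationError(f"cds_position must be >= 1, got {self.cds_position}")
        if self.cds_sequence is not None:
            seq = self.cds_sequence.upper()
            if self.cds_position > len(seq):
                raise ValidationError("cds_position beyond sequence end")
            found = seq[self.cds_position - 1]
            if found != self.ref_base.upper():
                raise ValidationError(
                    f"reference mismatch at c.{self.cds_position}: "
                    f"sequence has {found}, change states {self.ref_base}")

    @classmethod
    def from_hgvs(cls, hgvs: str, cds_sequence: str | None = None) -> "CodingChange":
        """Parse a simple substitution like 'c.1532G>A'."""
        body = hgvs.removeprefix("c.")
        try:
            pos_str = "".join(ch for ch in body if ch.isdigit())
            ref, alt = body[len(pos_str):].split(">")
            return cls(cds_position=int(pos_str), ref_base=ref, alt_base=alt,
                       cds_sequence=cds_sequence)
        except (ValueError, IndexError) as exc:
            raise ValidationError(f"cannot parse HGVS cDNA change {hgvs!r}") from exc


def cdna_to_codon(cds_position: int) -> tuple[int, int]:
    """Map a 1-based CDS position to (codon index, offset within codon).

    c.1532 falls in codon ceil(1532/3) = 511 at offset 2 — the residue the
    missense change replaces.
    """
    if cds_position < 1:
        raise ValidationError(f"cds_position must be >= 1, got {cds_position}")
    codon = math.ceil(cds_position / 3)
    offset = (cds_position - 1) % 3 + 1
    return codon, offset


def protein_consequence(change: CodingChange) -> str:
    """HGVS protein consequence of a cDNA substitution, e.g. p.Arg511His.

    Translates the affected codon before and after the change with the
    standard nuclear codon table; a synonymous change yields ``p.(=)``.
    """
    if change.cds_sequence is None:
        raise ValidationError("cds_sequence required for protein consequence")
    seq = change.cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} not divisible by 3")
    codon_idx, offset = cdna_to_codon(change.cds_position)
    start = (codon_idx - 1) * 3
    codon_before = seq[start:start + 3]
    codon_after = (codon_before[:offset - 1] + change.alt_base.upper()
                   + codon_before[offset:])
    aa_before = str(Seq(codon_before).translate(table=standard_dna_table))
    aa_after = str(Seq(codon_after).translate(table=standard_dna_table))
    if aa_before == aa_after:
        return "p.(=)"
    ref3 = "Ter" if aa_before == "*" else seq3(aa_before)
    alt3 = "Ter" if aa_after == "*" else seq3(aa_after)
    return f"p.{ref3}{codon_idx}{alt3}"


# ---------------------------------------------------------------------------
# ACMG-style evidence combination
# ---------------------------------------------------------------------------

PATHOGENIC_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = frozenset(
    {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)
VALID_CODES = PATHOGENIC_CODES | BENIGN_CODES


@dataclass
class EvidenceSet:
    codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [c for c in self.codes if c not in VALID_CODES]
        if unknown:
            raise ValidationError(f"unknown ACMG evidence codes: {unknown}")
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("duplicate evidence codes")

    def tally(self) -> dict[str, int]:
        counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
        for code in self.codes:
            prefix = code.rstrip("0123456789")
            counts[prefix] += 1
        return counts


def _is_pathogenic(n: dict[str, int]) -> bool:
    if n["PVS"] >= 1 and (n["PS"] >= 1 or n["PM"] >= 2
                          or (n["PM"] == 1 and n["PP"] == 1) or n["PP"] >= 2):
        return True
    if n["PS"] >= 2:
        return True
    if n["PS"] == 1 and (n["PM"] >= 3 or (n["PM"] == 2 and n["PP"] >= 2)
                         or (n["PM"] == 1 and n["PP"] >= 4)):
        return True
    return False


def _is_likely_pathogenic(n: dict[str, int]) -> bool:
    if n["PVS"] >= 1 and n["PM"] == 1:
        return True
    if n["PS"] == 1 and 1 <= n["PM"] <= 2:
        return True
    if n["PS"] == 1 and n["PP"] >= 2:
        return True
    if n["PM"] >= 3:
        return True
    if n["PM"] == 2 and n["PP"] >= 2:
        return True
    if n["PM"] == 1 and n["PP"] >= 4:
        return True
    return False


def _is_benign(n: dict[str, int]) -> bool:
    return n["BA"] >= 1 or n["BS"] >= 2


def _is_likely_benign(n: dict[str, int]) -> bool:
    return (n["BS"] == 1 and n["BP"] >= 1) or n["BP"] >= 2


def acmg_classify(evidence: EvidenceSet) -> str:
    """Combine evidence codes into a five-tier classification.

    Applies the published combining rules; an evidence set satisfying
    neither a pathogenic nor a benign rule — or satisfying both — is a
    variant of uncertain significance (VUS). PM2 (rare) plus BP4
    (computationally benign) resolves to VUS this way.
    """
    n = evidence.tally()
    pathogenic_side = _is_pathogenic(n) or _is_likely_pathogenic(n)
    benign_side = _is_benign(n) or _is_likely_benign(n)
    if pathogenic_side and benign_side:
        return "VUS"
    if _is_pathogenic(n):
        return "PATHOGENIC"
    if _is_likely_pathogenic(n):
        return "LIKELY_PATHOGENIC"
    if _is_benign(n):
        return "BENIGN"
    if _is_likely_benign(n):
        return "LIKELY_BENIGN"
    return "VUS"
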