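"""Seeded synthetic cohorts and assay datasets with ground-truth labels.

No patient data is distributed with this package, so every downstream stage
is exercised on synthetic inputs that emulate the study design: a
consanguineous nuclear family (two related founders, six offspring, one
affected child), an exome's heterozygous/homozygous variant strata with
controlled allele-frequency tiers and prediction scores, one planted causal
variant, and the three fibroblast assays (G/F actin fractionation band
intensities, actin-repolymerization puncta images, wound-healing mask
series).

Each generated variant carries a ground-truth fate — the cascade stage that
should remove it, or CAUSAL_CANDIDATE — derived from its stratum, so label
recovery by the real pipeline is a complete end-to-end check.

All randomness flows from one explicit seed through a single
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .cohort_io import (
    AggregatePrediction,
    AnnotationRecord,
    Cohort,
    Genotype,
    PedMember,
    Pedigree,
    Variant,
    build_cohort,
    write_annotations,
    write_ped,
    write_vcf,
)

PROBAND_ID = "II-3"

#: Default rarity thresholds the AF tiers are sampled around.
PUBLIC_AF_THRESHOLD = 0.001
INTERNAL_AF_THRESHOLD = 0.005


class ConfigError(ValueError):
    pass


class Fate(str, Enum):
    DROPPED_AF = "DROPPED_AF"
    DROPPED_INTERNAL = "DROPPED_INTERNAL"
    DROPPED_ARCHIVE = "DROPPED_ARCHIVE"
    DROPPED_BENIGN = "DROPPED_BENIGN"
    DROPPED_EXPRESSION = "DROPPED_EXPRESSION"
    DROPPED_CLINICAL = "DROPPED_CLINICAL"
    DROPPED_SEGREGATION = "DROPPED_SEGREGATION"
    DROPPED_KNOWN_PHENOTYPE = "DROPPED_KNOWN_PHENOTYPE"
    CAUSAL_CANDIDATE = "CAUSAL_CANDIDATE"


class AfTier(str, Enum):
    COMMON = "COMMON"                      # above the public rarity threshold
    RARE_PUBLIC_ONLY = "RARE_PUBLIC_ONLY"  # rare publicly, common internally
    RARE_EVERYWHERE = "RARE_EVERYWHERE"


@dataclass
class StratumSpec:
    """One homogeneous block of generated variants."""

    name: str
    count: int
    zygosity_in_proband: Genotype  # HET or HOM_ALT
    af_tier: AfTier
    in_internal_db: bool = False
    in_population_archives: bool = False
    damaging_scores: bool = True
    heart_expressed: bool = True
    segregates_AR: bool = True
    in_dcm_panel: bool = False
    clinical_mismatch: bool = False
    known_phenotype_gene: bool = False
    is_causal: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError(f"stratum {self.name}: count must be >= 0")
        if self.zygosity_in_proband not in (Genotype.HET, Genotype.HOM_ALT):
            raise ConfigError(f"stratum {self.name}: proband zygosity must be HET or HOM_ALT")


def expected_fate(stratum: StratumSpec) -> Fate:
    """The cascade stage expected to remove a stratum's variants.

    Mirrors the branch ordering: heterozygous variants meet the rarity,
    archive-presence and annotation-negation stages; homozygous variants
    meet public rarity, internal-database exclusion, expression/score
    negation, recessive segregation and known-phenotype exclusion.
    """
    if stratum.zygosity_in_proband == Genotype.HET:
        if stratum.af_tier != AfTier.RARE_EVERYWHERE:
            return Fate.DROPPED_AF
        if stratum.in_population_archives:
            return Fate.DROPPED_ARCHIVE
        if not stratum.heart_expressed:
            return Fate.DROPPED_EXPRESSION
        if not stratum.damaging_scores:
            return Fate.DROPPED_BENIGN
        if stratum.clinical_mismatch:
            return Fate.DROPPED_CLINICAL
        raise ConfigError(
            f"heterozygous stratum {stratum.name!r} would survive the whole "
            "het branch; the generator plants no het candidate")
    # homozygous branch
    if stratum.af_tier == AfTier.COMMON:
        return Fate.DROPPED_AF
    if stratum.in_internal_db:
        return Fate.DROPPED_INTERNAL
    if not stratum.heart_expressed:
        return Fate.DROPPED_EXPRESSION
    if not stratum.damaging_scores:
        return Fate.DROPPED_BENIGN
    if not stratum.segregates_AR:
        return Fate.DROPPED_SEGREGATION
    if stratum.known_phenotype_gene:
        return Fate.DROPPED_KNOWN_PHENOTYPE
    return Fate.CAUSAL_CANDIDATE


# ---------------------------------------------------------------------------
# Pedigree and panel fixtures
# ---------------------------------------------------------------------------

def make_family_pedigree() -> Pedigree:
    """Two consanguineous founders and six offspring, one affected (II-3)."""
    members = [
        PedMember("I-1", 1, None, None, affected=False),
        PedMember("I-2", 2, None, None, affected=False),
    ]
    for i in range(1, 7):
        iid = f"II-{i}"
        members.append(PedMember(iid, 1 if i % 2 else 2, "I-1", "I-2",
                                 affected=(iid == PROBAND_ID)))
    return Pedigree(members=members, consanguinity="founders are first cousins")


def default_dcm_panel() -> list[str]:
    """47 gene symbols standing in for the dilated-cardiomyopathy panel."""
    real = ["TTN", "LMNA", "MYH7", "MYH6", "TNNT2", "TNNI3", "TNNC1", "TPM1",
            "ACTC1", "DES", "SCN5A", "PLN", "RBM20", "BAG3", "FLNC", "DSP",
            "VCL", "MYBPC3", "LDB3", "TCAP", "CSRP3", "ACTN2", "NEXN", "ANKRD1",
            "TMPO", "SGCD", "DMD", "EMD", "FKTN", "LAMA4", "ILK", "CRYAB",
            "DOLK", "GATAD1", "EYA4", "PSEN1", "PSEN2", "ABCC9", "JPH2", "MYPN",
            "NEBL", "PRDM16", "TXNRD2", "DTNA", "TAZ", "LRRC10", "TBX20"]
    assert len(real) == 47
    return real


def write_panel(path: str | Path, genes: list[str] | None = None) -> None:
    genes = genes if genes is not None else default_dcm_panel()
    Path(path).write_text("\n".join(genes) + "\n")


def read_panel(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]


# ---------------------------------------------------------------------------
# Canonical cohort configuration
# ---------------------------------------------------------------------------

def canonical_strata() -> list[StratumSpec]:
    """Scaled-down exome strata mirroring the study's two filtering branches.

    Heterozygous side: a common background, three panel-gene variants
    carried by several healthy relatives, archived rare variants, and rare
    variants negated on benign scores / clinical mismatch / low cardiac
    expression — the branch ends empty. Homozygous side: common background,
    an internal-database block, five expression/score negations, five
    segregation failures, one known-phenotype gene, and the single planted
    causal variant.
    """
    HET, HOM = Genotype.HET, Genotype.HOM_ALT
    return [
        StratumSpec("het_common", 120, HET, AfTier.COMMON),
        StratumSpec("het_rare_internal_common", 10, HET, AfTier.RARE_PUBLIC_ONLY),
        StratumSpec("het_panel", 3, HET, AfTier.RARE_EVERYWHERE,
                    in_dcm_panel=True, in_population_archives=True),
        StratumSpec("het_archived", 8, HET, AfTier.RARE_EVERYWHERE,
                    in_population_archives=True),
        StratumSpec("het_benign", 3, HET, AfTier.RARE_EVERYWHERE,
                    damaging_scores=False),
        StratumSpec("het_clinical", 2, HET, AfTier.RARE_EVERYWHERE,
                    clinical_mismatch=True),
        StratumSpec("het_low_expression", 3, HET, AfTier.RARE_EVERYWHERE,
                    heart_expressed=False),
        StratumSpec("hom_common", 40, HOM, AfTier.COMMON),
        StratumSpec("hom_internal", 12, HOM, AfTier.RARE_EVERYWHERE,
                    in_internal_db=True),
        StratumSpec("hom_benign", 3, HOM, AfTier.RARE_EVERYWHERE,
                    damaging_scores=False),
        StratumSpec("hom_low_expression", 2, HOM, AfTier.RARE_EVERYWHERE,
                    heart_expressed=False),
        StratumSpec("hom_nonsegregating", 5, HOM, AfTier.RARE_EVERYWHERE,
                    segregates_AR=False),
        StratumSpec("hom_known_phenotype", 1, HOM, AfTier.RARE_EVERYWHERE,
                    known_phenotype_gene=True),
        StratumSpec("causal", 1, HOM, AfTier.RARE_EVERYWHERE, is_causal=True),
    ]


def printed_counts_strata() -> list[StratumSpec]:
    """Homozygous-branch strata sized to the study's printed stage totals:
    81 rare homozygous variants, 69 removed by the internal population
    database, 5 negated on expression/scores, 7 entering segregation."""
    HOM = Genotype.HOM_ALT
    return [
        StratumSpec("hom_rare_internal", 69, HOM, AfTier.RARE_EVERYWHERE,
                    in_internal_db=True),
        StratumSpec("hom_negated_benign", 3, HOM, AfTier.RARE_EVERYWHERE,
                    damaging_scores=False),
        StratumSpec("hom_negated_lowexpr", 2, HOM, AfTier.RARE_EVERYWHERE,
                    heart_expressed=False),
        StratumSpec("hom_nonsegregating", 5, HOM, AfTier.RARE_EVERYWHERE,
                    segregates_AR=False),
        StratumSpec("hom_known_phenotype", 1, HOM, AfTier.RARE_EVERYWHERE,
                    known_phenotype_gene=True),
        StratumSpec("causal", 1, HOM, AfTier.RARE_EVERYWHERE, is_causal=True),
    ]


#: Locus and annotation of the planted causal variant (chr6:144095295 G>A,
#: PHACTR2; SIFT 0.025, CADD 32, aggregate 0.925, gnomAD AF 3.611e-5).
CAUSAL_LOCUS = ("6", 144095295, "G", "A", "PHACTR2")
CAUSAL_SCORES = {"sift": 0.025, "cadd": 32.0, "aggregate_score": 0.925}
CAUSAL_GNOMAD_AF = 0.00003611


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_af(rng: np.random.Generator, threshold: float, rare: bool) -> float:
    """Uniform draw inside (0, 0.9*thr] if rare, else [1.1*thr, 10*thr]."""
    if rare:
        return float(rng.uniform(threshold * 1e-3, threshold * 0.9))
    return float(rng.uniform(threshold * 1.1, threshold * 10.0))


def _public_afs(rng: np.random.Generator, tier: AfTier) -> dict[str, float | None]:
    rare = tier in (AfTier.RARE_PUBLIC_ONLY, AfTier.RARE_EVERYWHERE)
    afs: dict[str, float | None] = {}
    for db in ("gnomAD", "1000Genomes", "ExAC", "EVS"):
        # some databases simply do not report rare variants
        if rare and db != "gnomAD" and rng.random() < 0.3:
            afs[db] = None
        else:
            afs[db] = _sample_af(rng, PUBLIC_AF_THRESHOLD, rare)
    return afs


def _genotypes(rng: np.random.Generator, stratum: StratumSpec,
               pedigree: Pedigree) -> dict[str, Genotype]:
    """Draw family genotypes consistent with the stratum's labels."""
    g: dict[str, Genotype] = {}
    proband = PROBAND_ID
    father, mother = pedigree.parents_of(proband)
    sibs = [m for m in pedigree.unaffected_ids if m not in (father, mother)]

    if stratum.zygosity_in_proband == Genotype.HET:
        g[proband] = Genotype.HET
        for p in (father, mother):
            g[p] = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF
        for s in sibs:
            g[s] = Genotype.HET if rng.random() < 0.3 else Genotype.HOM_REF
        if stratum.in_dcm_panel:
            # guarantee >= 4 healthy heterozygous carriers for AD negation
            healthy = [father, mother] + sibs
            for m in rng.choice(healthy, size=4, replace=False):
                g[m] = Genotype.HET
        return g

    g[proband] = Genotype.HOM_ALT
    g[father] = Genotype.HET
    g[mother] = Genotype.HET
    if stratum.segregates_AR:
        for s in sibs:
            g[s] = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF
    else:
        # at least one unaffected member homozygous for the alternate allele
        bad = set(rng.choice(sibs, size=int(rng.integers(1, 3)), replace=False))
        for s in sibs:
            if s in bad:
                g[s] = Genotype.HOM_ALT
            else:
                g[s] = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF
        if stratum.af_tier == AfTier.COMMON:
            # common variants may also be homozygous in a parent
            if rng.random() < 0.3:
                g[father] = Genotype.HOM_ALT
    return g


_BASES = ("A", "C", "G", "T")


def generate_cohort(strata: list[StratumSpec] | None = None,
                    pedigree: Pedigree | None = None,
                    seed: int = 0,
                    panel: list[str] | None = None,
                    ) -> tuple[Cohort, dict[str, Fate]]:
    """Generate a labelled synthetic cohort.

    Returns the joined :class:`~pedcascade.cohort_io.Cohort` and the
    ground-truth fate per variant key. Deterministic for a fixed seed.
    """
    strata = strata if strata is not None else canonical_strata()
    pedigree = pedigree or make_family_pedigree()
    panel = panel if panel is not None else default_dcm_panel()
    if not pedigree.affected_ids:
        raise ConfigError("pedigree has no affected member")
    causal_strata = [s for s in strata if s.is_causal]
    if len(causal_strata) > 1 or any(s.count != 1 for s in causal_strata):
        raise ConfigError("at most one causal stratum, with count 1")

    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    annotations: dict[str, AnnotationRecord] = {}
    truth: dict[str, Fate] = {}
    panel_cycle = iter(panel)
    gene_serial = 0

    for stratum in strata:
        fate = expected_fate(stratum)
        for _ in range(stratum.count):
            if stratum.is_causal:
                chrom, pos, ref, alt, gene = CAUSAL_LOCUS
            else:
                chrom = str(int(rng.integers(1, 23)))
                pos = int(rng.integers(10_000, 50_000_000))
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                if stratum.in_dcm_panel:
                    gene = next(panel_cycle)
                else:
                    gene_serial += 1
                    gene = f"GENE{gene_serial:04d}"
            v = Variant(chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                        gene=gene,
                        genotypes=_genotypes(rng, stratum, pedigree))
            if v.key in annotations:  # vanishingly rare locus collision
                continue

            if stratum.is_causal:
                af_public = {"gnomAD": CAUSAL_GNOMAD_AF, "1000Genomes": None,
                             "ExAC": None, "EVS": None}
                af_internal = None
                sift, cadd, agg = (CAUSAL_SCORES["sift"], CAUSAL_SCORES["cadd"],
                                   CAUSAL_SCORES["aggregate_score"])
                prediction = AggregatePrediction.NON_BENIGN
            else:
                af_public = _public_afs(rng, stratum.af_tier)
                if stratum.af_tier == AfTier.COMMON \
                        or stratum.af_tier == AfTier.RARE_PUBLIC_ONLY \
                        or stratum.in_internal_db:
                    af_internal = _sample_af(rng, INTERNAL_AF_THRESHOLD, rare=False)
                else:
                    af_internal = _sample_af(rng, INTERNAL_AF_THRESHOLD, rare=True)
                if stratum.damaging_scores:
                    sift = float(rng.uniform(0.0, 0.05))
                    cadd = float(rng.uniform(20.0, 40.0))
                    agg = float(rng.uniform(0.8, 1.0))
                    prediction = AggregatePrediction.NON_BENIGN
                else:
                    sift = float(rng.uniform(0.2, 0.9))
                    cadd = float(rng.uniform(0.0, 9.0))
                    agg = float(rng.uniform(0.0, 0.15))
                    prediction = AggregatePrediction.BENIGN

            annotations[v.key] = AnnotationRecord(
                key=v.key,
                af_public=af_public,
                af_internal=af_internal,
                in_internal_db=stratum.in_internal_db,
                present_in_population_archives=stratum.in_population_archives,
                sift=sift, cadd=cadd, aggregate_score=agg,
                aggregate_prediction=prediction,
                heart_expression=float(rng.uniform(5.0, 50.0))
                if stratum.heart_expressed else 0.0,
                clinical_mismatch=stratum.clinical_mismatch,
                known_phenotype_gene=stratum.known_phenotype_gene,
            )
            variants.append(v)
            truth[v.key] = fate

    variants.sort(key=lambda v: (int(v.chrom), v.pos, v.alt))
    cohort = build_cohort(variants, annotations, pedigree)
    return cohort, truth


def emit_cohort(cohort: Cohort, truth: dict[str, Fate], out_dir: str | Path,
                ) -> dict[str, Path]:
    """Write the cohort as VCF + PED + annotation TSV + panel + truth YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "family.ped",
        "annotations": out / "annotations.tsv",
        "panel": out / "dcm_panel.txt",
        "truth": out / "ground_truth.yaml",
    }
    write_vcf(paths["vcf"], cohort.variants, cohort.pedigree.ids)
    write_ped(paths["ped"], cohort.pedigree)
    write_annotations(paths["annotations"], cohort.annotations,
                      genes={v.key: v.gene for v in cohort.variants})
    write_panel(paths["panel"])
    paths["truth"].write_text(yaml.safe_dump(
        {k: f.value for k, f in truth.items()}, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Image emission (16-bit TIFF / PNG)
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a single-channel image as 16-bit TIFF or PNG.

    Float inputs are rounded and clipped to the uint16 range; boolean masks
    map to 0/65535.
    """
    path = Path(path)
    if image.dtype == bool:
        data = np.where(image, np.uint16(65535), np.uint16(0))
    else:
        data = np.clip(np.round(np.asarray(image, dtype=float)),
                       0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, data)
    else:
        raise ConfigError(f"unsupported image format {path.suffix!r}")


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def write_mask_series(path: str | Path, masks: np.ndarray) -> None:
    """Write a boolean (frames, H, W) stack as a multi-page 16-bit TIFF."""
    import tifffile

    data = np.where(np.asarray(masks, dtype=bool),
                    np.uint16(65535), np.uint16(0))
    tifffile.imwrite(Path(path), data)


def read_mask_series(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(Path(path)) > 0


# ---------------------------------------------------------------------------
# Synthetic structure fixture
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, x: float, y: float, z: float,
                   element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5d} {name_field} {resname:>3s} {chain}"
            f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}"
            f"{0.0:>6.2f}          {element:>2s}")


def synthetic_rpel_end_pdb() -> str:
    """PDB text of a synthetic stand-in for the end of an RPEL repeat.

    Not derived from any experimental structure: an arginine guanidinium
    (residue 511) is placed so that NH1 sits 2.8 A from a glutamate OE1
    (504) and 2.8 A from an aspartate OD1 (505), with further charged
    interactions inside the 4 A salt-bridge cutoff; backbone atoms are far
    from everything. Every contact is mediated by NE/NH1/NH2, so an
    arginine-to-histidine substitution eliminates all of them.
    """
    atoms = [
        ("N", "GLU", 504, 10.0, 10.0, 10.0, "N"),
        ("CA", "GLU", 504, 11.0, 10.0, 10.0, "C"),
        ("C", "GLU", 504, 12.0, 10.0, 10.0, "C"),
        ("O", "GLU", 504, 13.0, 10.0, 10.0, "O"),
        ("CB", "GLU", 504, 5.0, 1.0, 0.0, "C"),
        ("CG", "GLU", 504, 4.4, 0.6, 0.0, "C"),
        ("CD", "GLU", 504, 3.6, 0.4, 0.0, "C"),
        ("OE1", "GLU", 504, 2.8, 0.0, 0.0, "O"),
        ("OE2", "GLU", 504, 3.8, 1.2, 0.0, "O"),
        ("N", "ASP", 505, 10.0, 12.0, 10.0, "N"),
        ("CA", "ASP", 505, 11.0, 12.0, 10.0, "C"),
        ("C", "ASP", 505, 12.0, 12.0, 10.0, "C"),
        ("O", "ASP", 505, 13.0, 12.0, 10.0, "O"),
        ("CB", "ASP", 505, 0.4, 4.6, 0.0, "C"),
        ("CG", "ASP", 505, 0.4, 3.6, 0.0, "C"),
        ("OD1", "ASP", 505, 0.0, 2.8, 0.0, "O"),
        ("OD2", "ASP", 505, 1.2, 3.6, 0.0, "O"),
        ("N", "ARG", 511, 10.0, 14.0, 10.0, "N"),
        ("CA", "ARG", 511, 11.0, 14.0, 10.0, "C"),
        ("C", "ARG", 511, 12.0, 14.0, 10.0, "C"),
        ("O", "ARG", 511, 13.0, 14.0, 10.0, "O"),
        ("CB", "ARG", 511, -3.0, -2.0, 0.0, "C"),
        ("CG", "ARG", 511, -2.4, -1.6, 0.0, "C"),
        ("CD", "ARG", 511, -1.8, -1.2, 0.0, "C"),
        ("NE", "ARG", 511, -1.2, -0.8, 0.0, "N"),
        ("CZ", "ARG", 511, -0.4, -0.6, 0.0, "C"),
        ("NH1", "ARG", 511, 0.0, 0.0, 0.0, "N"),
        ("NH2", "ARG", 511, 0.2, -1.4, 0.0, "N"),
    ]
    lines = [_pdb_atom_line(i, spec[0], spec[1], "A", *spec[2:])
             for i, spec in enumerate(atoms, start=1)]
    return "\n".join(lines + ["END"]) + "\n"


# ---------------------------------------------------------------------------
# Assay simulation
# ---------------------------------------------------------------------------

@dataclass
class BandConfig:
    """Densitometry means for the G/F fractionation western blot.

    Defaults plant the study's direction of effect: the patient's globular
    (G) pool is halved at equal filamentous (F) signal, and GAPDH appears
    only in the supernatant when the separation worked.
    """

    control_g_mean: float = 1000.0
    control_f_mean: float = 1000.0
    patient_g_mean: float = 500.0
    patient_f_mean: float = 1000.0
    gapdh_supernatant_mean: float = 800.0
    gapdh_pellet_mean: float = 4.0   # near zero: separation success
    noise_cv: float = 0.08           # coefficient of variation, all bands
    separation_failure: bool = False

    def __post_init__(self) -> None:
        for name in ("control_g_mean", "control_f_mean", "patient_g_mean",
                     "patient_f_mean", "gapdh_supernatant_mean",
                     "gapdh_pellet_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


@dataclass
class PunctaConfig:
    """Poisson rates of residual unpolymerized-actin puncta per image.

    Timepoints are minutes after cytochalasin-D washout. Control cells
    repolymerize quickly (rates fall steeply); patient cells retain more
    puncta at every timepoint.
    """

    timepoints_min: tuple[int, ...] = (0, 15, 30, 60)
    control_rates: tuple[float, ...] = (40.0, 25.0, 12.0, 4.0)
    patient_rates: tuple[float, ...] = (70.0, 60.0, 48.0, 35.0)
    images_per_timepoint: int = 6    # n = 6 from three independent cultures
    image_shape: tuple[int, int] = (256, 256)
    puncta_radius: int = 3
    puncta_amplitude: float = 200.0
    background_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.control_rates + self.patient_rates):
            raise ConfigError("puncta rates must be >= 0")
        if len(self.control_rates) != len(self.timepoints_min) \
                or len(self.patient_rates) != len(self.timepoints_min):
            raise ConfigError("one rate per timepoint per group required")


@dataclass
class WoundConfig:
    """Kinematics of the scratch-wound fronts.

    Defaults map the 500 µm insert gap to 100 px (5 µm/px) imaged every
    20 min for 67 h. The control front speed closes the gap in ~30 h; the
    patient speed plus direction noise leaves it open at the end.
    """

    frame_shape: tuple[int, int] = (120, 240)
    gap_px: int = 100
    speed_px_per_frame: float = 0.55
    speed_noise_sd: float = 0.05
    frame_interval_min: float = 20.0
    um_per_px: float = 5.0

    def __post_init__(self) -> None:
        if self.gap_px >= self.frame_shape[1]:
            raise ConfigError("gap wider than frame")
        if self.frame_interval_min <= 0:
            raise ConfigError("frame interval must be > 0")
        if self.speed_px_per_frame < 0 or self.speed_noise_sd < 0:
            raise ConfigError("speeds must be >= 0")


#: Patient-like wound kinematics: slower net advance, noisier direction.
PATIENT_WOUND = dict(speed_px_per_frame=0.18, speed_noise_sd=0.12)


@dataclass
class AssaySimConfig:
    """Bundle of the three assay configurations plus the acquisition seed."""

    bands: BandConfig = field(default_factory=BandConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    wound_control: WoundConfig = field(default_factory=WoundConfig)
    wound_patient: WoundConfig = field(
        default_factory=lambda: replace(WoundConfig(), **PATIENT_WOUND))
    seed: int = 0


def generate_band_table(config: BandConfig, n_replicates: int, seed: int):
    """Simulated band-intensity table: 2 groups x n replicates x 4 bands.

    Returns a pandas DataFrame with columns group, replicate, G, F,
    GAPDH_supernatant, GAPDH_pellet. With ``noise_cv == 0`` intensities
    equal the configured means exactly.
    """
    import pandas as pd

    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    means = {
        "CONTROL": (config.control_g_mean, config.control_f_mean),
        "PATIENT": (config.patient_g_mean, config.patient_f_mean),
    }
    pellet_mean = (config.gapdh_supernatant_mean if config.separation_failure
                   else config.gapdh_pellet_mean)
    for group, (g_mean, f_mean) in means.items():
        for rep in range(1, n_replicates + 1):
            def draw(mu: float) -> float:
                if config.noise_cv == 0:
                    return mu
                return float(max(0.0, rng.normal(mu, config.noise_cv * mu)))
            rows.append({
                "group": group,
                "replicate": rep,
                "G": draw(g_mean),
                "F": draw(f_mean),
                "GAPDH_supernatant": draw(config.gapdh_supernatant_mean),
                "GAPDH_pellet": draw(pellet_mean),
            })
    return pd.DataFrame(rows)


def generate_puncta_image(rate: float, shape: tuple[int, int] = (256, 256),
                          seed: int = 0, radius: int = 3,
                          amplitude: float = 200.0,
                          background_noise_sd: float = 0.0,
                          ) -> tuple[np.ndarray, int]:
    """One synthetic puncta image and its true count.

    The count is drawn Poisson(rate); that many non-overlapping discs of
    the given radius are placed by rejection sampling on a (optionally
    noisy) dark background. Returns (float image, true count).
    """
    if rate < 0:
        raise ConfigError("rate must be >= 0")
    if shape[0] <= 0 or shape[1] <= 0:
        raise ConfigError(f"image shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    count = int(rng.poisson(rate))
    h, w = shape
    margin = radius + 1
    if h <= 2 * margin or w <= 2 * margin:
        raise ConfigError("image too small for the puncta radius")

    img = np.zeros(shape, dtype=float)
    if background_noise_sd > 0:
        img += np.abs(rng.normal(0.0, background_noise_sd, size=shape))

    yy, xx = np.mgrid[0:h, 0:w]
    centers: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    max_attempts = 200 * max(count, 1)
    while placed < count and attempts < max_attempts:
        attempts += 1
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        # non-overlapping (and non-touching) by rejection sampling
        if any((cy - py) ** 2 + (cx - px) ** 2 <= (2 * radius + 2) ** 2
               for py, px in centers):
            continue
        centers.append((cy, cx))
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = amplitude
        placed += 1
    if placed < count:
        raise ConfigError(
            f"could not place {count} non-overlapping puncta in {shape}")
    return img, count


def generate_timepoint_counts(config: PunctaConfig, seed: int,
                              ) -> dict[int, dict[str, list[int]]]:
    """Per-timepoint, per-group puncta counts via full image generation.

    Each count is obtained by generating a puncta image and recording its
    planted ground truth, so the values carry Poisson sampling noise.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, dict[str, list[int]]] = {}
    for i, t in enumerate(config.timepoints_min):
        out[t] = {"CONTROL": [], "PATIENT": []}
        for group, rates in (("CONTROL", config.control_rates),
                             ("PATIENT", config.patient_rates)):
            for _ in range(config.images_per_timepoint):
                _, n = generate_puncta_image(
                    rates[i], config.image_shape,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    radius=config.puncta_radius,
                    amplitude=config.puncta_amplitude,
                    background_noise_sd=config.background_noise_sd)
                out[t][group].append(n)
    return out


def generate_wound_series(config: WoundConfig, n_frames: int, seed: int,
                          ) -> tuple[np.ndarray, int | None]:
    """Binary mask series of two advancing wound fronts.

    The left front occupies columns ``[0, L_t)`` and the right front
    ``[W - R_t, W)``; both advance at the configured mean speed with
    per-frame Gaussian speed noise (clipped at zero — fronts never
    retract). Returns (masks of shape (n_frames, H, W), true first-contact
    frame index or None). Contact is the first frame whose integer front
    extents touch, i.e. ``L_t >= W - R_t``.
    """
    if n_frames < 2:
        raise ConfigError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    h, w = config.frame_shape
    start = (w - config.gap_px) / 2.0
    left = right = start
    masks = np.zeros((n_frames, h, w), dtype=bool)
    contact_frame: int | None = None
    for t in range(n_frames):
        if t > 0:
            left += max(0.0, rng.normal(config.speed_px_per_frame,
                                        config.speed_noise_sd))
            right += max(0.0, rng.normal(config.speed_px_per_frame,
                                         config.speed_noise_sd))
        li = min(int(round(left)), w)
        ri = min(int(round(right)), w)
        masks[t, :, :li] = True
        masks[t, :, w - ri:] = True
        if contact_frame is None and li >= w - ri:
            contact_frame = t
    return masks, contact_frame
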