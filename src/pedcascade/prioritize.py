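"""The two exome-filtering branches as an auditable cascade engine.

The heterozygous branch asks whether a dominant-acting variant could explain
the phenotype despite healthy parents: a rarity filter, a cardiomyopathy
gene-panel screen, a compound-heterozygote scan, then a de-novo residual
negated by archive presence and benign-looking annotations. The homozygous
branch assumes homozygosity by descent in the consanguineous pedigree:
rarity in public databases, exclusion by the population-specific internal
database, then negation on cardiac expression and damage-prediction scores,
handing the survivors to pedigree segregation.

Every stage records its input, exclusions (with the clause that fired) and
survivors, so each input variant is accounted for exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort_io import (
    AggregatePrediction,
    AnnotationRecord,
    Cohort,
    Genotype,
    LookupError_,
    Variant,
)

#: Negation clauses in evaluation order.
ALL_NEGATION_CLAUSES = ("expression", "scores", "benign_aggregate", "clinical")


class ConfigError(ValueError):
    pass


@dataclass
class FilterThresholds:
    """Rarity and benign-score thresholds of the filtering cascade.

    Frequencies are strict upper bounds ("less than"): a variant at exactly
    ``af_public_max`` is dropped. A variant is score-negated only if it looks
    benign on ALL THREE predictors (CADD below ``cadd_min``, aggregate damage
    score below ``aggregate_min`` AND SIFT above ``sift_max``); a missing
    score never satisfies a benign clause.
    """

    af_public_max: float = 0.001     # <0.1% in every public database
    af_internal_max: float = 0.005   # <0.5% in the internal population database
    cadd_min: float = 10.0
    aggregate_min: float = 0.2
    sift_max: float = 0.1
    heart_expression_min: float = 0.0  # drop iff expression <= this floor

    def __post_init__(self) -> None:
        for name in ("af_public_max", "af_internal_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("cadd_min", "aggregate_min", "sift_max", "heart_expression_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class Stage:
    name: str
    input_keys: list[str]
    survivors: list[str]
    dropped: dict[str, str]  # key -> reason

    @property
    def input_count(self) -> int:
        return len(self.input_keys)

    @property
    def excluded_count(self) -> int:
        return len(self.dropped)

    @property
    def surviving_count(self) -> int:
        return len(self.survivors)


@dataclass
class CascadeReport:
    """Ordered per-stage bookkeeping for one filtering branch."""

    branch: str  # HET, HOM or PANEL
    stages: list[Stage] = field(default_factory=list)
    side_reports: dict[str, object] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def add_stage(self, name: str, input_keys: list[str], survivors: list[str],
                  dropped: dict[str, str]) -> Stage:
        stage = Stage(name=name, input_keys=list(input_keys),
                      survivors=list(survivors), dropped=dict(dropped))
        if stage.surviving_count != stage.input_count - stage.excluded_count:
            raise AssertionError(f"stage {name}: survivors != input - excluded")
        if self.stages and self.stages[-1].survivors != stage.input_keys:
            raise AssertionError(f"stage {name}: input != previous survivors")
        self.stages.append(stage)
        return stage

    @property
    def final_survivors(self) -> list[str]:
        return self.stages[-1].survivors if self.stages else []

    def counts(self) -> list[dict]:
        return [{"stage": s.name, "input": s.input_count,
                 "excluded": s.excluded_count, "surviving": s.surviving_count}
                for s in self.stages]

    def all_drop_reasons(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.stages:
            out.update(s.dropped)
        return out

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "stages": [{"stage": s.name, "input": s.input_count,
                        "excluded": s.excluded_count,
                        "surviving": s.surviving_count,
                        "survivor_keys": s.survivors,
                        "dropped": s.dropped} for s in self.stages],
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# Stage predicates
# ---------------------------------------------------------------------------

def select_by_zygosity(cohort: Cohort, proband_id: str,
                       zygosity: Genotype) -> list[Variant]:
    """Variants whose proband genotype equals the requested class.

    MISSING proband genotypes are never selected, for either class.
    """
    if proband_id not in cohort.pedigree.ids:
        raise LookupError_(f"unknown sample id {proband_id!r}")
    if zygosity not in (Genotype.HET, Genotype.HOM_ALT):
        raise ConfigError(f"selectable zygosities are HET and HOM_ALT, got {zygosity}")
    return [v for v in cohort.variants
            if v.genotypes.get(proband_id) == zygosity]


def passes_af(ann: AnnotationRecord, thresholds: FilterThresholds,
              use_internal: bool) -> bool:
    """Strict "less than" rarity test; a missing frequency counts as rare."""
    for af in ann.af_public.values():
        if af is not None and af >= thresholds.af_public_max:
            return False
    if use_internal and ann.af_internal is not None \
            and ann.af_internal >= thresholds.af_internal_max:
        return False
    return True


def af_filter(variants: list[Variant], annotations: dict[str, AnnotationRecord],
              thresholds: FilterThresholds, use_internal: bool) -> list[Variant]:
    """Keep variants rarer than the public (and optionally internal) bounds."""
    return [v for v in variants
            if passes_af(annotations[v.key], thresholds, use_internal)]


def panel_screen(variants: list[Variant], gene_panel: list[str]) -> list[Variant]:
    """Subset of variants in known cardiomyopathy genes (case-insensitive)."""
    if not gene_panel:
        raise ConfigError("gene panel is empty")
    panel = {g.strip().upper() for g in gene_panel if g.strip()}
    return [v for v in variants if v.gene.upper() in panel]


def compound_het_genes(variants: list[Variant]) -> dict[str, list[Variant]]:
    """Genes carrying >= 2 distinct surviving heterozygous variants."""
    by_gene: dict[str, dict[str, Variant]] = {}
    for v in variants:
        if v.gene:
            by_gene.setdefault(v.gene, {})[v.key] = v
    return {g: list(vs.values()) for g, vs in by_gene.items() if len(vs) >= 2}


def archive_presence_filter(variants: list[Variant],
                            annotations: dict[str, AnnotationRecord]) -> list[Variant]:
    """De-novo screen: drop anything reported in the population archives."""
    return [v for v in variants
            if not annotations[v.key].present_in_population_archives]


def negation_reason(ann: AnnotationRecord, thresholds: FilterThresholds,
                    clauses: tuple[str, ...] = ALL_NEGATION_CLAUSES) -> str | None:
    """First negation clause a variant satisfies, or None if it survives.

    * ``expression`` — cardiac expression at or below the floor (missing
      expression is NOT negated: absence of evidence keeps the variant).
    * ``scores`` — benign on all three predictors simultaneously; missing
      scores never count as benign.
    * ``benign_aggregate`` — the aggregated prediction verdict is BENIGN.
    * ``clinical`` — the gene's known phenotype is incompatible.
    """
    for clause in clauses:
        if clause == "expression":
            if ann.heart_expression is not None \
                    and ann.heart_expression <= thresholds.heart_expression_min:
                return "expression"
        elif clause == "scores":
            benign_cadd = ann.cadd is not None and ann.cadd < thresholds.cadd_min
            benign_agg = ann.aggregate_score is not None \
                and ann.aggregate_score < thresholds.aggregate_min
            benign_sift = ann.sift is not None and ann.sift > thresholds.sift_max
            if benign_cadd and benign_agg and benign_sift:
                return "scores"
        elif clause == "benign_aggregate":
            if ann.aggregate_prediction == AggregatePrediction.BENIGN:
                return "benign_aggregate"
        elif clause == "clinical":
            if ann.clinical_mismatch:
                return "clinical"
        else:
            raise ConfigError(f"unknown negation clause {clause!r}")
    return None


def negation_filter(variants: list[Variant],
                    annotations: dict[str, AnnotationRecord],
                    thresholds: FilterThresholds,
                    clauses: tuple[str, ...] = ALL_NEGATION_CLAUSES,
                    ) -> tuple[list[Variant], dict[str, str]]:
    """Split variants into kept and dropped-with-reason by the clause set."""
    kept: list[Variant] = []
    dropped: dict[str, str] = {}
    for v in variants:
        reason = negation_reason(annotations[v.key], thresholds, clauses)
        if reason is None:
            kept.append(v)
        else:
            dropped[v.key] = reason
    return kept, dropped


# ---------------------------------------------------------------------------
# Branches
# ---------------------------------------------------------------------------

def _keys(variants: list[Variant]) -> list[str]:
    return [v.key for v in variants]


def run_het_branch(cohort: Cohort, panel: list[str],
                   thresholds: FilterThresholds | None = None,
                   proband_id: str | None = None) -> CascadeReport:
    """Heterozygous branch: rarity -> panel/compound-het side reports ->
    de-novo archive negation -> annotation negation (all clauses)."""
    thresholds = thresholds or FilterThresholds()
    proband_id = proband_id or _sole_affected(cohort)
    report = CascadeReport(branch="HET")
    report.metadata["negation_clauses"] = list(ALL_NEGATION_CLAUSES)

    het = select_by_zygosity(cohort, proband_id, Genotype.HET)
    all_keys = _keys(cohort.variants)
    report.add_stage("zygosity_select_het", all_keys, _keys(het),
                     {k: "not_het_in_proband" for k in all_keys if k not in set(_keys(het))})

    rare = af_filter(het, cohort.annotations, thresholds, use_internal=True)
    report.add_stage("af_filter", _keys(het), _keys(rare),
                     {k: "allele_frequency" for k in _keys(het)
                      if k not in set(_keys(rare))})

    # Side reports: candidate panel genes and compound-het genes do not
    # shrink the de-novo residual, they answer separate questions.
    report.side_reports["panel_screen"] = _keys(panel_screen(rare, panel))
    report.side_reports["compound_het_genes"] = {
        g: _keys(vs) for g, vs in compound_het_genes(rare).items()}

    unreported = archive_presence_filter(rare, cohort.annotations)
    report.add_stage("archive_presence_filter", _keys(rare), _keys(unreported),
                     {k: "reported_in_archives" for k in _keys(rare)
                      if k not in set(_keys(unreported))})

    kept, dropped = negation_filter(unreported, cohort.annotations, thresholds)
    report.add_stage("negation_filter", _keys(unreported), _keys(kept), dropped)
    return report


#: Clause subset used by the homozygous branch: the recessive negation rests
#: on cardiac expression and damage scores; known-phenotype exclusion happens
#: after segregation instead.
HOM_NEGATION_CLAUSES = ("expression", "scores")


def run_hom_branch(cohort: Cohort,
                   thresholds: FilterThresholds | None = None,
                   proband_id: str | None = None) -> CascadeReport:
    """Homozygous (homozygosity-by-descent) branch.

    HOM_ALT select -> public-database rarity -> internal-database exclusion
    -> expression/score negation -> hand-off set for segregation testing.
    """
    thresholds = thresholds or FilterThresholds()
    proband_id = proband_id or _sole_affected(cohort)
    report = CascadeReport(branch="HOM")
    report.metadata["negation_clauses"] = list(HOM_NEGATION_CLAUSES)

    hom = select_by_zygosity(cohort, proband_id, Genotype.HOM_ALT)
    all_keys = _keys(cohort.variants)
    report.add_stage("zygosity_select_hom", all_keys, _keys(hom),
                     {k: "not_hom_in_proband" for k in all_keys
                      if k not in set(_keys(hom))})

    rare = af_filter(hom, cohort.annotations, thresholds, use_internal=False)
    report.add_stage("af_filter_public", _keys(hom), _keys(rare),
                     {k: "allele_frequency" for k in _keys(hom)
                      if k not in set(_keys(rare))})

    not_internal = [v for v in rare if not cohort.annotations[v.key].in_internal_db]
    report.add_stage("internal_db_exclusion", _keys(rare), _keys(not_internal),
                     {k: "internal_db" for k in _keys(rare)
                      if k not in set(_keys(not_internal))})

    kept, dropped = negation_filter(not_internal, cohort.annotations, thresholds,
                                    clauses=HOM_NEGATION_CLAUSES)
    report.add_stage("negation_filter", _keys(not_internal), _keys(kept), dropped)

    report.metadata["segregation_handoff"] = _keys(kept)
    if not kept:
        report.metadata["status"] = "no candidate"
    return report


def _sole_affected(cohort: Cohort) -> str:
    affected = cohort.pedigree.affected_ids
    if len(affected) != 1:
        raise ConfigError(f"expected exactly one affected member, found {affected}")
    return affected[0]


def run_recessive_pipeline(cohort: Cohort,
                           thresholds: FilterThresholds | None = None,
                           proband_id: str | None = None) -> CascadeReport:
    """Full recessive adjudication: hom branch, then autosomal-recessive
    segregation across the pedigree, then known-phenotype gene exclusion.

    The final survivors are the likely-causative candidates (ideally one).
    """
    from .segregate_classify import SegregationModel, segregation_consistent

    report = run_hom_branch(cohort, thresholds, proband_id)
    handoff = [cohort.variant(k) for k in report.final_survivors]

    model = SegregationModel(mode="AR")
    segregating, seg_dropped = [], {}
    for v in handoff:
        ok, _ = segregation_consistent(v, cohort.pedigree, model)
        if ok:
            segregating.append(v)
        else:
            seg_dropped[v.key] = "segregation"
    report.add_stage("segregation_AR", _keys(handoff), _keys(segregating), seg_dropped)

    final = [v for v in segregating
             if not cohort.annotations[v.key].known_phenotype_gene]
    report.add_stage("known_phenotype_exclusion", _keys(segregating), _keys(final),
                     {k: "known_phenotype" for k in _keys(segregating)
                      if k not in set(_keys(final))})
    report.metadata["candidates"] = _keys(final)
    if not final:
        report.metadata["status"] = "no candidate"
    return report
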