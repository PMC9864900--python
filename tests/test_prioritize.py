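"""The filtering cascade: stage predicates, branch runs, audit properties."""

import pytest

from pedcascade import (
    AggregatePrediction,
    AnnotationRecord,
    Fate,
    FilterThresholds,
    Genotype,
    StratumSpec,
    Variant,
    af_filter,
    archive_presence_filter,
    build_cohort,
    compound_het_genes,
    generate_cohort,
    make_family_pedigree,
    negation_filter,
    panel_screen,
    run_het_branch,
    run_hom_branch,
    run_recessive_pipeline,
    select_by_zygosity,
)
from pedcascade.cohort_io import LookupError_
from pedcascade.prioritize import ConfigError, HOM_NEGATION_CLAUSES, passes_af
from pedcascade.synthetic_data import AfTier, PROBAND_ID, canonical_strata


def _ann(key="1:10:A:T", **kwargs):
    return AnnotationRecord(key=key, **kwargs)


def _variant(pos=10, gene="GENE1", proband_gt=Genotype.HET):
    return Variant("1", pos, "A", "T", gene=gene,
                   genotypes={PROBAND_ID: proband_gt})


class TestZygositySelect:
    def test_counts_match_strata(self, canonical):
        cohort, _ = canonical
        het_total = sum(s.count for s in canonical_strata()
                        if s.zygosity_in_proband == Genotype.HET)
        hom_total = sum(s.count for s in canonical_strata()
                        if s.zygosity_in_proband == Genotype.HOM_ALT)
        assert len(select_by_zygosity(cohort, PROBAND_ID, Genotype.HET)) == het_total
        assert len(select_by_zygosity(cohort, PROBAND_ID, Genotype.HOM_ALT)) == hom_total

    def test_missing_never_selected(self, family_pedigree):
        v = _variant(proband_gt=Genotype.MISSING)
        cohort = build_cohort([v], {v.key: _ann()}, family_pedigree)
        assert select_by_zygosity(cohort, PROBAND_ID, Genotype.HET) == []
        assert select_by_zygosity(cohort, PROBAND_ID, Genotype.HOM_ALT) == []

    def test_unknown_sample(self, canonical):
        cohort, _ = canonical
        with pytest.raises(LookupError_):
            select_by_zygosity(cohort, "NOBODY", Genotype.HET)


class TestAfFilter:
    thresholds = FilterThresholds()

    def test_candidate_frequency_kept(self):
        ann = _ann(af_public={"gnomAD": 0.00003611, "1000Genomes": None,
                              "ExAC": None, "EVS": None})
        assert passes_af(ann, self.thresholds, use_internal=True)

    def test_boundary_is_strict(self):
        ann = _ann(af_public={"gnomAD": 0.001})
        assert not passes_af(ann, self.thresholds, use_internal=False)
        ann_internal = _ann(af_internal=0.005)
        assert not passes_af(ann_internal, self.thresholds, use_internal=True)
        assert passes_af(ann_internal, self.thresholds, use_internal=False)

    def test_all_missing_kept(self):
        assert passes_af(_ann(), self.thresholds, use_internal=True)

    def test_any_public_db_can_fail(self):
        ann = _ann(af_public={"gnomAD": 1e-6, "EVS": 0.01})
        assert not passes_af(ann, self.thresholds, use_internal=False)


class TestPanelAndCompoundHet:
    def test_panel_case_insensitive(self):
        variants = [_variant(pos=1, gene="Ttn"), _variant(pos=2, gene="NOPE")]
        assert [v.gene for v in panel_screen(variants, ["TTN"])] == ["Ttn"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigError):
            panel_screen([_variant()], [])

    def test_no_match_empty(self):
        assert panel_screen([_variant(gene="AAA")], ["BBB"]) == []

    def test_compound_het_detects_shared_gene(self):
        v1, v2 = _variant(pos=1, gene="GENE_X"), _variant(pos=2, gene="GENE_X")
        v3 = _variant(pos=3, gene="GENE_Y")
        result = compound_het_genes([v1, v2, v3])
        assert set(result) == {"GENE_X"}
        assert {v.key for v in result["GENE_X"]} == {v1.key, v2.key}

    def test_duplicate_key_not_counted_twice(self):
        v = _variant(gene="GENE_X")
        assert compound_het_genes([v, v]) == {}

    def test_canonical_cohort_has_no_compound_het(self, canonical):
        cohort, _ = canonical
        het = select_by_zygosity(cohort, PROBAND_ID, Genotype.HET)
        rare = af_filter(het, cohort.annotations, FilterThresholds(),
                         use_internal=True)
        assert compound_het_genes(rare) == {}


class TestArchiveAndNegation:
    def test_archive_presence(self):
        present = _variant(pos=1)
        absent = _variant(pos=2)
        anns = {present.key: _ann(present.key, present_in_population_archives=True),
                absent.key: _ann(absent.key)}
        assert archive_presence_filter([present, absent], anns) == [absent]

    def test_damaging_candidate_kept(self):
        ann = _ann(sift=0.025, cadd=32.0, aggregate_score=0.925,
                   heart_expression=12.0,
                   aggregate_prediction=AggregatePrediction.NON_BENIGN)
        v = _variant()
        kept, dropped = negation_filter([v], {v.key: ann}, FilterThresholds())
        assert kept == [v] and dropped == {}

    def test_benign_on_all_three_scores_dropped(self):
        ann = _ann(cadd=5.0, aggregate_score=0.1, sift=0.5, heart_expression=10.0)
        v = _variant()
        kept, dropped = negation_filter([v], {v.key: ann}, FilterThresholds())
        assert kept == []
        assert dropped[v.key] == "scores"

    def test_missing_score_is_not_benign(self):
        ann = _ann(cadd=5.0, aggregate_score=0.1, sift=None, heart_expression=10.0)
        v = _variant()
        kept, _ = negation_filter([v], {v.key: ann}, FilterThresholds())
        assert kept == [v]

    def test_expression_floor(self):
        ann = _ann(heart_expression=0.0, cadd=30.0)
        v = _variant()
        kept, dropped = negation_filter([v], {v.key: ann}, FilterThresholds())
        assert dropped[v.key] == "expression"
        # missing expression is kept (absence of evidence)
        ann2 = _ann(heart_expression=None, cadd=30.0)
        kept2, _ = negation_filter([v], {v.key: ann2}, FilterThresholds())
        assert kept2 == [v]

    def test_hom_branch_clauses_skip_clinical(self):
        ann = _ann(clinical_mismatch=True, heart_expression=10.0, cadd=30.0)
        v = _variant()
        kept, _ = negation_filter([v], {v.key: ann}, FilterThresholds(),
                                  clauses=HOM_NEGATION_CLAUSES)
        assert kept == [v]
        _, dropped = negation_filter([v], {v.key: ann}, FilterThresholds())
        assert dropped[v.key] == "clinical"


class TestBranches:
    def test_het_branch_ends_empty_on_canonical(self, canonical):
        cohort, _ = canonical
        report = run_het_branch(cohort, ["TTN", "LMNA", "MYH7"])
        assert report.final_survivors == []
        assert len(report.side_reports["panel_screen"]) == 3

    def test_stage_arithmetic(self, canonical):
        cohort, _ = canonical
        for report in (run_het_branch(cohort, ["TTN"]), run_hom_branch(cohort)):
            for prev, nxt in zip(report.stages, report.stages[1:]):
                assert prev.survivors == nxt.input_keys
            for s in report.stages:
                assert s.surviving_count == s.input_count - s.excluded_count
                assert s.surviving_count <= s.input_count

    def test_common_only_cohort_empties_after_af(self):
        strata = [StratumSpec("common", 20, Genotype.HET, AfTier.COMMON)]
        cohort, _ = generate_cohort(strata, seed=3)
        report = run_het_branch(cohort, ["TTN"])
        for stage in report.stages[2:]:
            assert stage.surviving_count == 0

    def test_hom_branch_counts_match_ground_truth(self, canonical):
        cohort, truth = canonical
        report = run_recessive_pipeline(cohort)
        reasons = report.all_drop_reasons()
        reason_to_fate = {
            "not_hom_in_proband": None, "allele_frequency": Fate.DROPPED_AF,
            "internal_db": Fate.DROPPED_INTERNAL,
            "expression": Fate.DROPPED_EXPRESSION, "scores": Fate.DROPPED_BENIGN,
            "segregation": Fate.DROPPED_SEGREGATION,
            "known_phenotype": Fate.DROPPED_KNOWN_PHENOTYPE,
        }
        for key, reason in reasons.items():
            expected = reason_to_fate[reason]
            if expected is not None:
                assert truth[key] == expected, key
        assert [truth[k] for k in report.final_survivors] == [Fate.CAUSAL_CANDIDATE]

    def test_causal_removed_gives_no_candidate(self, canonical):
        cohort, truth = canonical
        causal = next(k for k, f in truth.items() if f == Fate.CAUSAL_CANDIDATE)
        cohort.annotations[causal].in_internal_db = True
        try:
            report = run_recessive_pipeline(cohort)
            assert report.metadata.get("status") == "no candidate"
            assert report.all_drop_reasons()[causal] == "internal_db"
        finally:
            cohort.annotations[causal].in_internal_db = False

    def test_audit_completeness(self, canonical):
        """Every input variant is a final survivor or dropped exactly once."""
        cohort, _ = canonical
        report = run_recessive_pipeline(cohort)
        dropped = report.all_drop_reasons()
        survivors = set(report.final_survivors)
        assert survivors.isdisjoint(dropped)
        assert survivors | set(dropped) == {v.key for v in cohort.variants}


class TestCascadeProperties:
    def test_af_threshold_monotonicity(self, canonical):
        """Tightening the public AF bound never increases any stage count."""
        cohort, _ = canonical
        grid = [0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00001]
        prev_counts = None
        for af_max in grid:
            report = run_hom_branch(
                cohort, FilterThresholds(af_public_max=af_max))
            counts = [s.surviving_count for s in report.stages]
            if prev_counts is not None:
                assert all(c <= p for c, p in zip(counts, prev_counts))
            prev_counts = counts

    def test_brute_force_oracle_small_cohorts(self):
        """Independent per-variant predicate evaluation matches the cascade."""
        strata = [
            StratumSpec("common", 10, Genotype.HOM_ALT, AfTier.COMMON),
            StratumSpec("internal", 5, Genotype.HOM_ALT, AfTier.RARE_EVERYWHERE,
                        in_internal_db=True),
            StratumSpec("benign", 5, Genotype.HOM_ALT, AfTier.RARE_EVERYWHERE,
                        damaging_scores=False),
            StratumSpec("lowexpr", 4, Genotype.HOM_ALT, AfTier.RARE_EVERYWHERE,
                        heart_expressed=False),
            StratumSpec("het_bg", 20, Genotype.HET, AfTier.COMMON),
            StratumSpec("causal", 1, Genotype.HOM_ALT, AfTier.RARE_EVERYWHERE,
                        is_causal=True),
        ]
        for seed in range(3):
            cohort, _ = generate_cohort(strata, seed=seed)
            assert len(cohort.variants) <= 50
            thresholds = FilterThresholds()
            report = run_hom_branch(cohort, thresholds)

            expected = set()
            for v in cohort.variants:  # independent flat re-evaluation
                ann = cohort.annotations[v.key]
                if v.genotypes[PROBAND_ID] != Genotype.HOM_ALT:
                    continue
                if any(af is not None and af >= thresholds.af_public_max
                       for af in ann.af_public.values()):
                    continue
                if ann.in_internal_db:
                    continue
                if ann.heart_expression is not None and ann.heart_expression <= 0:
                    continue
                if (ann.cadd is not None and ann.cadd < 10
                        and ann.aggregate_score is not None
                        and ann.aggregate_score < 0.2
                        and ann.sift is not None and ann.sift > 0.1):
                    continue
                expected.add(v.key)
            assert set(report.final_survivors) == expected
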