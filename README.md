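# pedcascade

Variant prioritization for a consanguineous dilated-cardiomyopathy (DCM)
pedigree, with the downstream analyses that turn one surviving variant into
a characterized candidate: pedigree segregation testing, ACMG-style
evidence combination, a zero-observation carrier-frequency bound,
cDNA-to-protein consequence mapping, structural contact-loss assessment of
a missense substitution, and quantification of three fibroblast assays
(G/F actin fractionation, actin-repolymerization puncta, wound healing).

## Who this is for

Groups analysing exomes from consanguineous families with a single affected
child, where the working model is **homozygosity by descent** of a recessive
allele: both copies of a rare variant inherited from a shared ancestor. The
package implements the whole adjudication chain as auditable, tested code,
driven by a synthetic-data module with per-variant ground-truth labels — so
every stage can be validated end to end without access to patient data.

## The filtering model

Starting from a multi-sample VCF, a 6-column PED pedigree and a TSV
annotation table, two branches run as ordered cascades in which every stage
records its inputs, exclusions (with the clause that fired) and survivors:

**Heterozygous branch** (could a dominant-acting variant explain disease
despite healthy parents?): select proband-heterozygous variants → keep only
those with allele frequency < 0.1% in every public database (gnomAD,
1000 Genomes, ExAC, EVS) *and* < 0.5% in the internal population database →
screen a 47-gene DCM panel and scan for compound heterozygotes (side
reports) → negate everything reported in population archives (de-novo
hypothesis) → negate on benign annotations (aggregated predictor verdict,
all-three-benign scores CADD < 10, aggregate score < 0.2, SIFT > 0.1, low
cardiac expression, incompatible clinical phenotype).

**Homozygous branch** (homozygosity by descent): select
proband-homozygous variants → public rarity (< 0.1%) → exclusion of
variants present in the internal population exome database → negation on
cardiac expression and damage scores → autosomal-recessive segregation
across the pedigree (affected child homozygous, both parents carriers, no
unaffected homozygote) → exclusion of genes with known incompatible
phenotypes → the causal candidate.

Frequency bounds are strict (`<`); a missing frequency or score is a
distinct state that never counts against a variant (absent means rare, and
missing scores are never "benign"). The allele never observed in N surveyed
chromosomes gets the frequency upper bound 1/N.

## Worked example

```python
import pedcascade as pc

cohort, truth = pc.generate_cohort(seed=1)     # 213-variant labelled cohort
report = pc.run_recessive_pipeline(cohort)
for s in report.counts():
    print(s)
print("candidates:", report.metadata["candidates"])
```

prints

```
{'stage': 'zygosity_select_hom', 'input': 213, 'excluded': 149, 'surviving': 64}
{'stage': 'af_filter_public', 'input': 64, 'excluded': 40, 'surviving': 24}
{'stage': 'internal_db_exclusion', 'input': 24, 'excluded': 12, 'surviving': 12}
{'stage': 'negation_filter', 'input': 12, 'excluded': 5, 'surviving': 7}
{'stage': 'segregation_AR', 'input': 7, 'excluded': 5, 'surviving': 2}
{'stage': 'known_phenotype_exclusion', 'input': 2, 'excluded': 1, 'surviving': 1}
candidates: ['6:144095295:G:A']
```

— of 64 proband-homozygous variants, 24 are rare publicly, 12 survive the
internal database, 7 survive score/expression negation and enter
segregation, 2 segregate correctly, and after removing the gene already
tied to a different disorder a single candidate remains: the planted
chr6:144095295 G>A missense variant. Its characterization:

```python
pc.carrier_frequency_bound([780, 77])          # -> (1714, 0.000583...)
pc.cdna_to_codon(1532)                         # -> (511, 2)
pc.acmg_classify(pc.EvidenceSet(["PM2", "BP4"]))  # -> 'VUS'
```

The bound says an allele unseen in 780 + 77 surveyed individuals has
frequency below 1 in 1714 chromosomes; cDNA position 1532 maps to codon
511 (an Arg→His change, `p.Arg511His`); and rare-in-populations (PM2)
combined with computationally-benign (BP4) evidence resolves to a variant
of uncertain significance under the combining rules.

The same workflow is available from the shell (`pedcascade run`,
`pedcascade segregate`, `pedcascade acmg`, `pedcascade carrier-bound`,
`pedcascade consequence`, `pedcascade contacts`).

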