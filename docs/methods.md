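# Methods

This note documents the models, parameter choices and numerical decisions
behind `pedcascade`, and what the synthetic-data-driven tests do and do not
demonstrate about real data.

## Cohort model and filtering cascade

A cohort joins three inputs keyed by `chrom:pos:ref:alt`: decomposed
bi-allelic variants with per-sample genotype classes (HOM_REF / HET /
HOM_ALT / MISSING; unphased, so 0/1 ≡ 1/0), an annotation record per
variant, and a pedigree. Multi-allelic VCF records are split into one
variant per ALT allele; alleles other than the ALT under consideration
count as reference for that decomposed variant.

Missingness is a first-class state. An absent allele frequency passes
rarity filters (a variant not reported in a population database is treated
as rare — the candidate variant itself is absent from most databases), and
a missing prediction score can never satisfy a "benign" clause. This
asymmetry is deliberate: the cascade removes variants only on positive
evidence of commonness or benignity.

Thresholds (defaults): public allele frequency < 0.001 in **every** public
database; internal population database frequency < 0.005; score negation
fires only when a variant looks benign on *all three* predictors
(CADD < 10 **and** aggregate damage score < 0.2 **and** SIFT > 0.1) —
conjunctive because the predictors frequently disagree and the source
procedure retains variants with discordant tool outputs; expression
negation drops a variant only when cardiac expression is at or below a
configurable floor (default exactly 0), since "low expression" is not
quantified anywhere. All frequency comparisons are strict, matching the
"less than" wording of the thresholds; boundary behaviour is tested with
exact-threshold fixtures.

The heterozygous branch treats the gene-panel screen and the
compound-heterozygote scan as *side reports*: they answer separate
questions (known-gene dominant disease; two hits in one gene) and do not
shrink the de-novo residual. The homozygous branch applies only the
expression and score clauses at its negation stage; the known-phenotype
exclusion (a gene already associated with an incompatible disorder) runs
*after* segregation, matching the order in which such candidates are
actually eliminated. The archive-presence de-novo screen uses a boolean
"reported anywhere" flag rather than a frequency, because presence of even
one archived observation contradicts a de-novo hypothesis.

`CascadeReport` enforces its own bookkeeping: per stage,
survivors = input − excluded, and stage k's input is stage k−1's survivor
list, so every input variant ends in exactly one place — the final
survivor set or a dropped-with-reason record.

## Segregation models

* **AR** — the affected child is HOM_ALT, both parents HET, and no
  unaffected member HOM_ALT. Members with missing genotypes are skipped
  and listed; a missing proband genotype is an error.
* **DE_NOVO** — proband carries the allele, both parents HOM_REF.
* **AD_NEGATION** — a putative dominant variant is negated once ≥ 4
  unaffected relatives (configurable) carry it.

The checker is verified against an independent literal enumeration of the
rule over random genotype assignments on the 8-member pedigree.

## Carrier bound, consequence mapping, evidence combination

The carrier-frequency bound is the zero-observation rule: unseen in
2 × Σ individuals = N chromosomes ⇒ frequency < 1/N. The surveyed
default is the two population-specific collections (780 + 77 individuals
→ 1714 chromosomes); a 95% confidence bound (3/N) was deliberately not
used, to match the "less than 1 in N" convention.

cDNA position → codon: codon = ⌈pos/3⌉, offset = ((pos−1) mod 3) + 1;
position 1532 → codon 511, offset 2. Protein consequence translates the
affected codon before/after with the standard nuclear codon table and
emits three-letter HGVS (`p.Arg511His`); synonymous changes give `p.(=)`.

ACMG-style classification implements only the published combining rules
over the 28 evidence codes (deriving per-criterion evidence is out of
scope). Sets satisfying neither side, or both sides, are VUS — which is
how {PM2, BP4} resolves.

## Structural contacts

Contacts are distance-only: hydrogen bond = side-chain donor (N/O with H
capacity) to acceptor (N/O) ≤ 3.5 Å; salt bridge = Arg/Lys/His positive
group atom to Asp/Glu carboxylate oxygen ≤ 4.0 Å. Angle criteria are
omitted because crystal structures at typical resolution lack hydrogens;
both cutoffs are configurable and conventional. Substitution impact uses
atom-name intersection: the replacement side chain keeps only atoms whose
names exist in its canonical atom set, and contacts are recomputed — no
rotamer building, repacking or energetics. For Arg→His this removes NE,
CZ, NH1 and NH2, and with them every guanidinium-mediated interaction;
that geometric elimination, not a modelled histidine conformation, is the
statement the module makes. The packaged test geometry is synthetic
(`synthetic_rpel_end_pdb`), built so the guanidinium contacts two acidic
side chains at hand-checkable distances; no experimental structure is
distributed.

## Assay quantification

**G/F ratio.** Per replicate, ratio = G / F band intensity. QC excludes
any replicate whose pellet GAPDH exceeds `qc_tolerance` (default 0.1) ×
supernatant GAPDH — GAPDH in the pellet means the fractionation failed.
Group comparison defaults to Mann–Whitney U (consistent with the
nonparametric framework; the original comparison's test is unstated),
switchable to Welch's t.

**Puncta counting.** Otsu threshold (standing in for unstated ImageJ
settings, configurable to a fixed threshold) → 8-connected components →
keep components of 4–400 px² → count. A constant image counts 0. On
noise-free synthetic images the count equals the planted ground truth
exactly; with background noise it remains exact for the default disc
amplitude because the discs dominate the threshold.

**Kruskal–Wallis + Dunn.** The omnibus test is scipy's tie-corrected
Kruskal–Wallis per recovery timepoint. Dunn's post-test is implemented
here (no installed package provides it): z = (R̄ᵢ − R̄ⱼ) / √([N(N+1)/12 −
Στ(t³−t)/(12(N−1))](1/nᵢ + 1/nⱼ)), two-sided normal p, Bonferroni-adjusted
by the k(k−1)/2 comparisons (the post-test's adjustment variant is
unstated; Bonferroni is the default and configurable). Significance marks
follow the source legend verbatim (* ≤ 0.005, ** ≤ 0.001, *** ≤ 0.0005,
overall criterion p < 0.05) even though those cutoffs are unconventional;
`conventional=True` switches to 0.05/0.01/0.001.

**Wound healing.** Contact time: frame 0 must contain exactly two
disjoint regions; every pixel is assigned to its nearest initial region by
Euclidean distance transform, and contact is the first frame in which one
8-connected component contains pixels of both assignments, converted to
hours via the frame interval (default 20 min). Coverage: each frame is
split 3×3 (remainder pixels join the last row/column, keeping the split
area-conserving); the per-square covered fractions and their
area-weighted mean are reported at 5 h intervals, so the mean equals the
whole-frame covered fraction exactly.

## Synthetic-data generator

The generator emulates the study design, not raw instruments: no
read-level simulation, no linkage structure, no photorealistic microscopy.
Its defaults are the study conditions wherever stated, and module choices
(flagged below) where the source gives no number.

* **Pedigree**: two consanguineous founders + six offspring, one affected
  (II-3) — the only segregation surface available.
* **Cohort strata**: each stratum fixes proband zygosity, an
  allele-frequency tier, database-presence flags, score/expression labels,
  segregation behaviour and panel membership; the expected cascade fate is
  derived from those labels, giving 100% label-recovery checks. AF tiers
  are drawn uniformly inside (0, 0.9·threshold] or [1.1·threshold,
  10·threshold] to keep random draws away from the strict-inequality
  boundary (boundary semantics are tested with exact fixtures instead).
  The canonical cohort is scaled down from exome size (213 variants) with
  stage proportions preserved; the printed-totals fixture
  (`printed_counts_strata`) reproduces the 81 → 12 → 7 homozygous-branch
  bookkeeping exactly. The planted causal variant carries the reported
  locus (chr6:144095295 G>A), gnomAD frequency 3.611e-5 and scores
  (SIFT 0.025, CADD 32, aggregate 0.925); HOM_ALT in the proband, HET in
  both parents, never HOM_ALT in unaffected members.
* **Band intensities**: Gaussian noise at 8% CV around group means with
  the patient G pool halved (direction from the study; magnitudes are
  module choices). A separation-failure flag moves GAPDH into the pellet
  so QC must reject.
* **Puncta images**: counts ~ Poisson(rate); non-overlapping discs placed
  by rejection sampling (making the true count unambiguous); rates per
  timepoint (control 40/25/12/4, patient 70/60/48/35 at 0/15/30/60 min,
  n = 6 images) are module choices reproducing "higher residual puncta in
  patient at every timepoint" at the stated n.
* **Wound masks**: two flat fronts advance with clipped-Gaussian per-frame
  speeds; 500 µm gap ↦ 100 px (5 µm/px), 20-min frames, 201 frames = 67 h.
  Control speed 0.55 px/frame closes the gap in ~30–35 h; the patient
  configuration (0.18 px/frame, higher speed noise — slower *net* advance
  standing in for slower, less directed migration) leaves it open at 67 h.
  The true contact frame is computed from the same integer front positions
  used to draw the masks, so the image-based contact detector can be held
  to exact agreement.

All randomness in any generator call flows from a single
`numpy.random.Generator` seeded explicitly; identical seeds give
byte-identical emitted files.

**What passing tests show** — that the cascade logic, segregation rules,
counting and kinematic measurements are correct against ground truth and
independent oracles. **What they do not show** — performance on real
exomes (no calling artefacts, no population structure, no annotation
disagreement between databases) or on real microscopy (no uneven
illumination, touching puncta, ragged fronts or cell retraction).

## Problem sizes

The test suite and acceptance script use the canonical 213-variant cohort
(10 seeds for recovery checks), ≤ 50-variant cohorts for brute-force
oracle comparison, 512×512 puncta images, and 201-frame 120×240 wound
series; the full acceptance run completes in seconds.

## Known limitations

* Autosomal models only (no X-linked or imprinting logic); no ROH
  detection from genotype runs — homozygosity is taken from genotypes.
* ACMG classification combines caller-supplied codes; it derives none.
* Contact detection has no angular terms and treats His as protonated on
  both ring nitrogens (both are listed as donors/positives).
* The wound model's fronts never retract and are spatially flat; contact
  time on real DIC-derived masks will be noisier than the generator
  suggests.
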