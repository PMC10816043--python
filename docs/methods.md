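# Methods

## Problem and model

`modscreen` screens a small, deeply phenotyped cohort carrying a fully
penetrant monogenic disease for *modifier* variants that segregate with a
particular disease outcome.  The unit of analysis is one phenotype (e.g.
adrenocortical tumour) screened over several positive *subgroups* — all
affected members of one family, or one unrelated affected patient —
against a single shared panel of symptom-negative controls.  Using family
subgroups removes a large fraction of the shared genetic background;
unrelated singleton subgroups probe whether a signal generalises beyond
one family.  A signal is only reported as a cohort-level candidate when it
recurs in **every** subgroup (shared genes / shared pathways), which is a
deliberately conservative intersection rather than a meta-analysis.

## Cohort and design rules

Patients carry per-phenotype flags `positive`, `negative` or `unknown`
("n/d" in the cohort table).  Design validation enforces:

* positives must be phenotype-positive, controls phenotype-negative; an
  `unknown` flag bars a patient from either role in that analysis;
* controls must be at least `min_control_age` years old (default 40 —
  the age by which nearly all disease manifestations are expected, so a
  younger patient cannot yet be called symptom-negative).  The rule
  deliberately applies only to controls: young symptomatic patients are
  valid cases;
* at most one member of any family may sit in the control panel;
* a multi-member subgroup must belong to a single family.

Designs are supplied explicitly in config and validated, never inferred
from the phenotype flags: control panels in small cohorts involve
judgement calls (e.g. using an unrelated carrier of the same pathogenic
variant as background for a family) that should be stated, not guessed.

## Genotype semantics

Variants are reduced to per-sample zygosity states
(`hom_ref`/`het`/`hom_alt`/`missing`) per bi-allelic alternate allele.
Multi-allelic records are split per alt; splitting conserves each sample's
total alternate-allele count.  Phase is ignored; half-calls (`./1`) are
treated as missing; haploid calls keep presence semantics (`1` → hom_alt).
These conventions are the package's own, stated substitutes for details
that commercial variant-analysis suites leave undocumented.

## Segregation filter

For one subgroup with positive calls P and control calls N:

* presence rule: every p ∈ P is a carrier (het or hom_alt) **and** every
  n ∈ N is hom_ref;
* zygosity rule: every p ∈ P is hom_alt **and** every n ∈ N is het.

Both clauses quantify over *all* samples, so by default (`strict`) any
missing call in P or N fails the variant for that subgroup.  The
`ignore_negatives` policy instead drops missing controls, requiring at
least one informative control; missing positives always fail.  The
zygosity rule requires **all** controls heterozygous (the literal
reading), not merely non-hom-alt.  The two rules demand contradictory
control states, so they are mutually exclusive, and a passing variant
never shares a zygosity state across arms — asserted as a post-condition
and proven exhaustively in the tests (all 4^6 assignments for 3 × 3
samples).

## Damaging consensus

Seven voting units: SIFT, LRT, MutationTaster, PolyPhen-2 (HumDiv and
HumVar merged), MutationAssessor, FATHMM, and a merged meta-predictor
voter (MetaSVM/MetaLR).  A merged voter votes damaging if any of its
tools does.  Binarisation of categorical labels is table-driven
(`data/predictor_vocab.tsv`): damaging = {damaging, possibly_damaging,
probably_damaging, deleterious, disease_causing,
disease_causing_automatic, medium, high}; everything else in a tool's
vocabulary — including LRT's `unknown` non-call — is a neutral vote, and
a tool with no label abstains.  Abstentions count against the threshold
(the denominator is fixed at 7): the rule demands positive indication by
at least `k` tools, so absence of evidence is not evidence of damage.
`possibly_damaging` and MutationAssessor `medium` count as damaging
because they are predicted-impact calls.  `k` defaults to 3 and is
configurable for sensitivity analyses; numeric scores are out of scope —
only categorical calls are consumed.

## Enrichment and shared signatures

Overrepresentation uses the one-sided Fisher exact test, computed as the
hypergeometric survival function P(X ≥ k) with universe size N, set size
K (clipped to the universe), and query size n (after dropping query genes
outside the universe, which are logged).  FDR is Benjamini–Hochberg,
applied per collection; q is floored at p.  The default background
universe is every gene carrying at least one annotated variant in the
joined input — an explicit, logged choice, overridable with a universe
file, since enrichment p-values are meaningless without a stated
universe.  The same Fisher test is used uniformly for GO-style and
pathway-style collections; gene sets are flat (no GO-graph propagation,
no pathway topology).

A set counts as *hit* in a subgroup when at least one surviving gene lies
in it; it is *shared* when hit in every subgroup, and *significant
shared* when additionally p < α (default 0.05, on the unadjusted p, the
convention used for cross-subgroup shading of pathway results) in every
subgroup.  Shared genes are the exact symbol intersection of the
per-subgroup lists (case-folded to upper).

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, with
defaults fixed at the study conditions used throughout the tests: two
families of sizes (3, 2) plus five unrelated patients; 200 background
variants with MAF ~ Uniform(0.01, 0.5); per-voter spurious damaging-label
probability 0.02; one planted presence-rule modifier with 4 damaging
votes at population frequency 0.3691 (modelled on a common Toll-like
receptor missense modifier) for the adrenal-style layout, and two
partially overlapping modifiers (so that no gene is shared by all
subgroups) for the pituitary-style layout.

* **Families** are two unobserved founders with the observed members as
  siblings: genotypes are founder draws from Hardy–Weinberg followed by
  Mendelian allele transmission.  Real pedigrees mix sib/parent-child
  relationships; a two-founder nuclear family is used because no pedigree
  topology is part of the cohort description.
* **Planted variants** override the random draw deterministically
  (targets carry per their rule, controls and non-target positives take
  the rule's complementary state), which guarantees the truth table;
  their founders are set het/het so every required child genotype remains
  Mendelian-possible.  Internally contradictory plant requests raise an
  error.
* **Labels**: planted variants receive exactly their configured number of
  damaging voters (chosen at random); background variants receive
  damaging labels independently per voter with the noise probability.
  Voter noise is independent — real predictors are correlated, so the
  synthetic false-positive rate is, if anything, optimistic in the
  low-noise regime.
* **Gene sets**: one planted set containing all modifier genes padded
  with random background genes to 18 members, plus decoy sets of random
  background genes.
* All variants are autosomal and in linkage equilibrium; there is no
  read-level simulation and no realistic site-frequency spectrum.  Same
  seed and config give byte-identical output files.

Passing planted-recovery tests therefore demonstrates the pipeline's
logic (filtering, consensus, intersection, bookkeeping) under the stated
noise model — not robustness to pedigree errors, correlated predictors,
population structure, or calling artefacts in real exomes.

The replicate study in the tests checks recovery against a closed-form
oracle: the chance a background variant falsely survives one subgroup is
P(segregation pattern under HWE/Mendelian sampling) × P(≥ 3 of 7 voters
spuriously damaging), the first factor computed by enumerating founder
genotype pairs.  At the default conditions the expected number of false
survivors per run is ≈ 10⁻³–10⁻², so mean recall is 1.0 and mean
precision ≈ 1.0.

## Numerical and degenerate-input choices

* Fisher p is clipped into (0, 1]; k = 0 gives p = 1.
* BH on an empty p-list returns an empty list; p-values must lie in
  (0, 1].
* Gene symbols are uppercased for all set operations; gene-list order is
  first genomic occurrence.
* An empty segregation call-list, an empty background universe, and
  fewer than two subgroups in an intersection are errors, not defaults.
* Sorting uses natural chromosome order (numeric where possible).
* The pipeline manifest contains no timestamps, so re-running an
  identical config is byte-identical; inputs are recorded by SHA-256.

## Known limitations

Only the two stated segregation clauses are implemented — no
recessive/compound-het models, no de-novo detection, no penetrance
modelling.  Predictor labels are inputs; no predictor is re-implemented.
MAF is carried as annotation, not used as a filter.  With single-gene
query lists the Fisher test cannot reach conventional significance, so
`significant shared pathways` is typically empty on minimal synthetic
runs; that is a property of the statistic, not a defect.  Test problem
sizes (200 background variants, 10 samples, tens of replicates) are
chosen to make the oracles exhaustive and the suite fast while keeping
every code path exercised.
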