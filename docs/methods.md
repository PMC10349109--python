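# Methods

## The triage model

The pipeline formalizes candidate-gene discovery in a minimal
tumor/germline exome design as pure set algebra over variant presence.
Let S be the cohort's samples, partitioned by manifest into discovery
tumors T, discovery blood (PBMC) B, normal tissues N, validation tumors
V and lab-control exomes L, and let P(v) ⊆ S be the samples in which
variant v was called. After the per-variant screen (below),

* hereditary candidates: T ⊆ P(v) ∧ B ⊆ P(v) ∧ P(v) ∩ N = ∅
* somatic candidates:   T ⊆ P(v) ∧ P(v) ∩ B = ∅ ∧ P(v) ∩ N = ∅

Presence is genotype-blind (Het and Hom both count); zygosity is carried
to reports only. The two predicates are contradictory on B, so the
candidate sets are disjoint whenever B ≠ ∅ — a property test asserts
this on random presence matrices.

Assumptions worth making explicit: calls are trusted as given (no
quality re-weighting), "present in the tumors" means present in *every*
discovery tumor (a `tumor_presence="any"` switch relaxes this), and all
samples were processed comparably enough that cross-sample absence is
informative.

## Screening conditions

A variant must simultaneously be (1) exonic or splicing, (2) of a
protein-affecting functional class (nonsynonymous, frameshift, splicing,
stopgain, stoploss, unknown), and (3–5) rarer than `maf_threshold`
(default 10⁻³, strict `<`) or absent in *each* configured population
database (default: 1000 Genomes East-Asian, ESP6500, ExAC). Missingness
is a first-class state parsed from ".", "", "NA": absence from a
population catalogue argues for rarity and therefore passes (the
`missing_passes` flag makes the conservative alternative available).
Equality with the threshold fails; a single too-common database entry
excludes the variant. The filters commute and are idempotent, which the
suite checks by permuting predicate order.

## Systematic errors and control subtraction

The identical normalized variant observed in `min_patients` (default 2)
distinct *unrelated* patients is removed as a platform artifact.
Counting is per patient, not per sample, and excludes the discovery-arm
patients: a hereditary candidate is by construction carried by every
discovery patient, so recurrence is only evidence of artifact when it
appears in patients whose genomes are otherwise independent of the
hypothesis (the validation and control arms). `exclude_discovery=False`
restores literal all-arms counting for designs where that is wanted.
Control-database subtraction is an exact set difference on normalized
variant keys; locus-level (allele-blind) matching was considered and
rejected because the artifact signature is the *same* allele recurring.

Variant identity everywhere is the normalized (chrom, pos, ref, alt):
alleles uppercased, shared suffix then shared prefix trimmed keeping one
anchor base. This is reference-free left normalization; true
left-alignment against a genome is out of scope since no reference
sequence is consumed.

## Predictor consensus

Six predictors vote damaging under SIFT < 0.1, PolyPhen-2 ∈ {D, P},
PhyloP > 0.95, GERP++ > 4, MutationTaster ∈ {A, D}, LRT = D; consensus
requires `min_votes` (default 4). Numeric comparisons are strict, so
boundary scores do not vote. A missing predictor abstains rather than
voting benign — coercing missing to 0 would make an unscored variant
look SIFT-damaging, which is why `PredictorScores` refuses to conflate
the two. Votes are monotone in evidence strength.

## ACMG/AMP combining

The 2015 combining criteria are encoded as data: rule lists per tier
over the strength-category counts (PVS/PS/PM/PP and BA/BS/BP). The
pathogenic and benign tiers are evaluated independently and then
resolved by a profile:

* `intervar_default` (default): a pathogenic tier of likely-pathogenic
  or stronger co-occurring with *any* benign evidence degrades to
  uncertain significance; a fired benign tier overrides a pathogenic
  side that reached only uncertain. This profile is reverse-engineered
  from published default-parameter InterVar outputs (it is the only
  resolution consistent with {PM2, BP4, BP7} → likely benign) and is
  labeled as such.
* `strict_acmg`: any co-occurrence of fired tiers → uncertain.

Code assignment is an input, not computed. An exhaustive test compares
all evidence sets of size ≤ 3 against an independently hand-written
restatement of the rule table.

## Expression gate

RPKM = reads · 10⁹ / (length · depth). Credibility bins: < 1 not
credible, [1, 10) background, [10, 100) middle, ≥ 100 high. The stated
bin edges leave exactly 1 and exactly 10 unassigned; left-closed
half-open intervals are adopted, and the "high" bin is added to make the
function total. The gate keeps a candidate gene when the bin of its
aggregated control RPKM is ≥ `min_bin` (default middle — background-level
expression is not treated as credible support). Aggregation across
samples is the arithmetic mean by default (an "average decrease" is the
quantity of interest), with median available; the percent change is
computed on aggregated values rather than averaging per-sample changes —
the two differ under unequal library depths, and the aggregated form is
the one that reduces to a plain fold change. The 2^−ΔΔCt fold change and
the 0.5·L·S² ellipsoid tumor volume (mm³; errors if the diameters are
swapped) are included as companion formulas.

## Synthetic cohort generator

Defaults encode the emulated study design: 2 discovery tumors (patients
D1, D2), 1 discovery blood (D2), 3 normal atria, 26 validation patients,
2 lab-control exomes; 1000 background variants, 50 common variants,
5 recurrent artifacts, 2 planted hereditary drivers, 0 somatic. Planted
drivers satisfy every screen condition, carry ≥ 4 damaging votes, and
their genes get control-tissue RPKM drawn from [15, 60) (middle bin)
with a case fold change of 0.34 — a 66 % decrease, the magnitude of the
emulated discovery. Artifacts carry the hereditary presence pattern plus
recurrence in 2–5 validation patients. Common variants draw at least one
database frequency ≥ 10⁻³; background variants violate ≥ 1 screen
condition, chosen at configured rates (0.4/0.4/0.5 for
region/function/frequency). Background MAFs mix a point mass of
missingness (0.35) with a heavy-tailed Beta(0.2, 5); background
predictor scores are missing with probability 0.15 and damaging with
probability 0.25 otherwise. Expression uses 2·10⁷ mapped reads per
library and gene lengths uniform on [1000, 5000] bp, with counts rounded
to integers (so realized RPKM deviates from its target by sub-percent
rounding only).

Randomness flows from one master seed through named child streams
(variant keys, placement, scores, expression), making outputs
byte-identical per config and insensitive to adding artifact classes.
Positions live on a synthetic contig `chrS` to avoid implying real
coordinates.

What the generator does *not* emulate: read-level error, allele-fraction
/ tumor-purity effects, linkage between variants, annotation mistakes,
batch effects between arms, and realistic per-exome variant counts
(defaults are desk-scale, ~10³ loci; the config scales up). Passing
recovery tests therefore demonstrates the *logic* is faithful — exact
recall of anything matching the planted patterns and exact rejection of
anything violating them — not that the pipeline is robust to calling
noise it never sees.

## Problem sizes and numerics

The test suite and the acceptance script run the recovery experiment on
20 seeds × 1000 background variants, the triage-vs-brute-force
equivalence on 100 random mini-cohorts (≤ 50 variants × ≤ 10 samples),
and the voter check on all 3⁶ coarse predictor states; the whole suite
completes in a few seconds on one CPU. RPKM values are exact IEEE-754
expressions of the defining ratio (validated to 10⁻⁹ relative); no
iterative numerics are involved anywhere, so there are no convergence
parameters. Variant tables round-trip losslessly through both dialects;
the VCF dialect transports numeric annotations as strings because VCF
INFO floats are single-precision, which would silently perturb stored
frequencies.

## Known limitations

* Evidence-code assignment and annotation itself are inputs; the package
  classifies and filters, it does not annotate.
* The InterVar-style conflict profile reproduces observed default
  behavior on the documented cases; other implementations' edge-case
  handling may differ.
* Headline gene/locus counts of any real study depend on its raw data
  and in-house control exomes; with synthetic cohorts this package
  measures the procedure's correctness, not those historical counts.
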