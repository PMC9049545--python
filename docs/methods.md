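# Methods

This note records the models, conventions and numerical choices behind
`mutopt`, and what the synthetic-data generators do and do not emulate.

## Substitution classification

Single-base substitutions are annotated by their immediate 5' and 3'
neighbours and collapsed onto the strand where the mutated base is a
pyrimidine (COSMIC SBS96 convention): if the central base of the observed
trinucleotide is a purine, the trinucleotide and the alternate base are
reverse-complemented. This gives 6 substitution types × 16 flank pairs = 96
classes; each class is reachable from exactly two strand representations,
and classification is invariant under reverse complement. Class labels and
row order follow the COSMIC SBS96 file layout (substitution-type-major,
then 5' flank, then 3' flank, each in A/C/G/T order). The pyrimidine
convention itself is a choice — the assays report strand-of-read — and is
fixed here for interoperability with COSMIC signature files.

## MDS spectra

Maximum-depth sequencing reports, per animal × amplicon position ×
alternate base, the fraction of consensus reads carrying the substitution.
Two technical filters are applied to the *sequenced-strand* representation,
before canonicalization:

* sequenced-strand C>T and G>T calls are removed — a known single-strand
  chemistry artifact of the assay, visible as high frequency on one strand
  without support on its complement;
* frequencies above an outlier ceiling (default 2 × 10⁻⁵, configurable)
  are removed.

The spectrum value for a class is the arithmetic mean frequency over every
surviving observation assigned to it, with zero-frequency assayed
observations included — "averaged across all positions in all animals"
read literally, so each (animal, position, alt) observation has equal
weight. Two documented alternatives are available: `per_animal_first`
averages within animals before across animals (protects against unequal
site counts per animal), and `nonzero_only` drops zero-frequency rows (the
reading in which only detected substitutions are averaged). Classes with
no surviving observation are reported as 0 rather than missing.

## WES spectra

Tumor SNV catalogs are converted to per-tumor class-count proportions
first, and the spectrum is the unweighted mean of the per-tumor vectors.
This ordering matters: a hypermutated tumor does not dominate the cohort
spectrum, unlike pooled counting. Tumors contribute only if they have at
least one SNV; an entirely empty catalog is an error because there is
nothing to normalize.

## Mutagenic optimality

Mean frequencies are small (10⁻⁷–10⁻⁵), so scores are reported per million:
the background (vehicle-control) score is the control mean × 10⁶, the
carcinogen score is (treated − control) × 10⁶ with negatives preserved
(classes the treatment depletes stay negative), and the ratio score divides
the two. The ratio denominator is floored at ε = 10⁻³ on the per-million
scale — small enough that it only engages for classes essentially absent
from the control arm, where the ratio is dominated by the numerator anyway;
every floor application is logged. Candidate mutations are called
*carcinogen-concordant* when their class's carcinogen score exceeds its
background score. This identity-line rule is a convention for automation —
the underlying comparison is a two-dimensional scatter with no natural
statistical test — and the rule used is recorded in run-all output
metadata.

## Driver prioritization

The ladder encodes "truncal mutation in a human-cancer-relevant gene at a
human-mutated position". Thresholds live in one `FilterConfig` with these
defaults: 5% VAF call floor; germline flags for known-SNP positions,
identical SNVs shared by ≥ 2 samples of one genotype group, ≥ 2 SNVs
within 100 bp in one sample, VAF exactly 100%, and identical SNVs in > 8
samples; clonality band = mean ± 3 sample (n−1) SD of the cohort's
reference-driver VAFs, clipped to [0, 1]; relative band 50–150% of the
tumor's reference-driver VAF; gene-level human recurrence ≥ 5 patients;
final relative floor 65%; initiating-driver promotion at ≥ 11 patients
("more than ten") with the identical amino-acid change.

Choices the thresholds do not themselves determine:

* *Group sharing*: "appearing together in the same group" is
  operationalized as identical SNV in at least two samples with the same
  group label (count configurable) — conservative, and the reason the
  synthetic cohort spreads recurrent hotspot drivers across groups (below).
* *Coordinate clustering*: ≥ 2 SNVs within a 100 bp window in one sample,
  both flagged; the window is configurable since no canonical value exists.
* *Reference driver*: a tumor is reference-mutant if it carries any
  non-synonymous SNV in a configured reference-gene set (Kras/Braf by
  default); the highest such VAF is the reference. Tumors without one use
  their own highest surviving candidate as reference, so a single strong
  candidate is never self-excluded.
* *Conservation*: "position conserved and mutated in human" is implemented
  as presence of the position in the recurrence catalog (any change), or
  the identical change being catalogued; no alignment-based conservation
  score is computed, and output metadata says so.
* *Strictness*: the cancer-gene branch VAF floor is strict (>), following
  "higher than"; band membership is inclusive.
* Degenerate configurations (all bands maximal, recurrence minimum 0)
  disable the catalog-dependent stages entirely, reducing the ladder to
  "non-synonymous and not a SNP" — useful as an algebraic sanity check.

Every SNV accumulates a trail of (stage, passed, reason) tuples up to the
stage that rejected it, and the full trail table is exported alongside the
driver list.

## Signature concordance

Exposures are refitting outputs (fractional mutation counts per signature
per tumor). The three-step contribution computation — proportions, then
p·S products, then column normalization so each class's shares sum to 1 —
is followed literally for the burden estimate: burden_c ∝ Σ_k E_k·w_{k,c}.
The algebraically natural alternative (burden_c ∝ Σ_k E_k·S_{k,c}, i.e.
exposure-weighted signature mixture without the intermediate
normalization) is available as `burden_mode="simple"`; the two differ
whenever signatures overlap unevenly across classes, and the test suite
demonstrates a case. Neither is asserted to be uniquely correct; the
default is the literal reading.

The concordance score is the burden proportion at the driver's class. The
mismatch score takes the signature with the largest share of the driver's
class (ties broken lexicographically and logged) and subtracts its overall
exposure proportion: 0 for single-signature tumors by construction,
approaching 1 when a near-absent signature is the only plausible source of
the driver. Tumors whose driver class no active signature can produce get
concordance 0 and a `class_unreachable` flag rather than being dropped;
all-zero exposure rows are skipped with a warning.

Hotspot driver protein changes are mapped to classes through a frozen
codon-context table derived from the reference coding sequences (KRAS
codons 12/13/19/61 with flanks GGT·GGC, TTG, GGT·CAA·GAG; BRAF codon 600
GTG). The mouse Braf V637E entry is the homolog of human BRAF V600E with
the same coding-strand change (GTG→GAG, class G[T>A]G); mouse Kras hotspot
windows match the human contexts. KRAS Q61H is stored as the c.183A>T
allele, with the A>C allele under a separate key, since both occur in
human tumors but map to different classes.

## Synthetic data

The generators emulate the *statistical structure* the analyses assume, not
real genomes:

* **MDS**: sites are the interior positions of an embedded synthetic
  amplicon (diverse trinucleotide contexts, several CAA sites so the
  default planted class T[T>A]G is assayable). Each animal × site × alt
  frequency is a binomial draw at fixed consensus depth (default 10⁶) from
  a flat 10⁻⁶ per-site background, with configured classes fold-enriched
  in the treated arm (default: T[T>A]G at 10×). Sequenced-strand C>T/G>T
  rows are generated at inflated rates to exercise the artifact filter,
  and a configurable fraction of rows is set above the outlier ceiling;
  ground truth flags exactly the removable rows. Defaults — 5 animals per
  arm, 20 sites, depth 10⁶, 10× enrichment — are the conditions under
  which argmax recovery is evaluated.
* **Tumors**: 23 tumors, each with exactly one clonal driver (truncated
  normal VAF, mean 0.45, SD 0.05 — straddling a mean ± 3 SD band of
  roughly 16–72%) drawn from a fixed allele mix (Kras Q61L ×6, Q61R ×4,
  G12D ×5, Q61H ×3, Braf V637E ×5), Poisson(8) subclonal passengers
  (Beta(2, 23) VAFs, mean 0.08, in invented genes; a minority of passenger
  genes are given recurrence entries so the catalog stages are
  non-trivial), and one germline decoy SNP per genotype group at VAF ≈ 0.5
  or 1.0. Tumors are distributed over 8 genotype groups with driver
  alleles spread so no identical driver SNV recurs within a group —
  recurrent hotspot drivers must not be mistaken for shared germline
  variants by the group-sharing rule, mirroring cohorts where recurrent
  drivers span genotype groups.
* **Exposures**: signature definitions are symmetric-Dirichlet(0.5) draws
  plus one designated minor signature concentrating 90% of its mass on the
  class least producible by the others. Per tumor, one random signature
  receives a 0.9 exposure share; driver classes are drawn from the
  dominant signature's distribution, or — for a configured fraction of
  tumors — set to the minor signature's peak class with the minor
  signature planted at a 5% share. Total burden is uniform on [100, 500)
  mutations.

What passing tests on these data do *not* show: robustness to real
sequencing error models, mapping artifacts, copy-number-distorted VAFs,
inter-animal rate heterogeneity, correlated signature definitions, or
refitting noise in exposures. The generators are calibrated to the
designed separations (clonal vs subclonal VAF, 10× enrichment, 90% vs 5%
exposure), so the recovery rates measure the pipeline's correctness under
those conditions, not its power on marginal real data.

## Numerical conventions

Proportion vectors are validated to sum to 1 within 10⁻⁹; signature file
columns are accepted within 10⁻⁴, renormalized with a warning within
10⁻², rejected beyond. VAF columns with values above 1 are interpreted as
percentages (logged). Degenerate inputs: identical reference VAFs give a
zero-width band with a warning; empty MDS input gives an all-zero spectrum
with a warning; empty SNV catalogs are an error for spectrum building and
an empty result for the ladder. All tabular outputs use fixed column order
and stable sorts, so identical inputs reproduce identical bytes.

Problem sizes used by the test suite and the acceptance script — 100 MDS
replicates, 50 tumor cohorts of 23 tumors, 100 exposure tumors, 100–200
randomized algebra fixtures — were chosen as the smallest sets at which
the binomial/Poisson sampling noise of the planted effects is negligible
relative to the thresholds being checked.
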