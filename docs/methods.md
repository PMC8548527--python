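# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic-data generators do and do not emulate, and the
numerical conventions. Internal coordinates are 0-based half-open; VCF and
pileup I/O convert to/from 1-based at the boundary.

## Ancient-DNA fragment and damage model

`synthetic_data.simulate_adna_fragments` draws endogenous fragment lengths
from a log-normal distribution parameterized by the arithmetic mean
(default 90 bp) and a log-scale dispersion σ (default 0.25): μ = ln(mean) −
σ²/2, so the configured mean is the distribution mean. A log-normal was
chosen because degraded-DNA length profiles are short and right-skewed; the
exact family is a modelling choice, and the length-recovery tests only
constrain the mean. Fragments are placed uniformly, half on each strand.

Deamination follows the standard single-exponential terminal approximation:
at position *i* (1-based) from the 5′ end, a reference C is read as T with
probability `terminal_ct_rate · decay^(i−1)`; the 3′ end carries the
mirror-image G→A process, and the two ends are independent. Defaults:
`terminal_ct_rate` 0.0217 (a typical position-1 level for a medieval-age
sample), `decay` 0.5 per position. In `udg_mode="partial"` the enzyme has
removed internal uracils, so damage survives only at the terminal base of
each end — exactly position 1, nothing inward. Contaminant ("modern")
fragments, drawn with probability `contamination_fraction`, carry no
damage. Every read's damage events, strand, origin and contaminant status
go into the truth record, so estimator tests always compare against what
was actually simulated, never against re-derived expectations.

Not emulated: indel damage, quality strings, non-uniform sequencing error,
mappability structure. Consequently a passing damage-recovery test shows
the estimator's conditional-frequency arithmetic and orientation handling
are right; it says nothing about alignment artefacts in real data.

## Misincorporation profiling

`authentication.compute_misincorporation_profile` reports, for each
position in a window (default 15) from each fragment end, mismatches /
opportunities — the fraction of reads whose *reference* base is C (5′,
read T) or G (3′, read A) at that position. For reverse-strand alignments
the (ref, read) pairs are complemented and reversed so damage is measured
in original-molecule orientation. Positions with zero opportunities are
reported as NaN rather than 0: on tiny inputs "no data" must not read as
"no damage". The `other_subst` field (mismatch rate outside the terminal
C→T/G→A cells) is the background against which interior positions of a
UDG-treated library should be judged. Alignment statistics apply mapping
quality ≥ 30; base-quality filtering is the caller's responsibility since
simulated reads carry no qualities.

## Molecular sex (Ry)

Ry = nY/(nX+nY) with SE = sqrt(ry(1−ry)/(nX+nY)). Classification requires
the whole 95% interval on one side: ry + 1.96·SE < 0.016 ⇒
consistent-with-XX; ry − 1.96·SE > 0.075 ⇒ consistent-with-XY; anything
else is indeterminate, as are totals below 100 alignments (with a
warning). The cutoffs are the published operating thresholds of the
alignment-count sexing method. The generator allocates reads binomially
with a male Y share of 0.09 (relative Y vs X+Y mappable length) and a
female Y mismapping rate of 0.002.

## Mitochondrial contamination likelihood

For pileup bases restricted to diagnostic sites (endogenous consensus ≠
contaminant allele), the per-base likelihood is the two-component mixture
(1−c)·P(b | endo, e) + c·P(b | contaminant pool, e) with P(b | allele, e) =
1−e if b equals the allele else e/3. The log-likelihood is evaluated on
the grid c ∈ {0, 0.001, …, 1} (the estimator *is* the grid search, and a
brute-force per-read implementation in the tests confirms the argmax). The
standard error is curvature-based: the central second difference of the
log-likelihood at the (interior-clamped) maximum, SE = (−d²ℓ/dc²)^(−1/2).
A flat likelihood returns SE 0.5 with a warning. The error rate defaults
to 0.01 and is a parameter, not an estimate. This is deliberately a
single-round estimator over a fixed contaminant frequency table; iterative
consensus refinement is out of scope and the method tag (`mt-likelihood`)
records which estimator produced a number.

## X-heterozygosity contamination

For a male (single X), estimate = max(0, pooled mismatch rate at
polymorphic X sites − pooled rate at monomorphic flanking sites). The SE
is a delete-one-block jackknife (default 20 blocks) applied *jointly* to
polymorphic and monomorphic blocks, because the background rate is itself
estimated and its sampling variance must propagate. Calibration over 400
independent replicates at truth 0.02 (1344 sites × 30×): mean jackknife SE
7.1×10⁻⁴ vs empirical SD 7.2×10⁻⁴; 2·SE coverage ≈ 94% (the few points
below the nominal 95.4% are the cost of estimating the SE from 20 blocks).
The method refuses female samples, for which it is undefined. The matching
generator plants the contaminant on the alternate allele at every
polymorphic site and uses an error rate of 0.001, the scale expected after
base-quality ≥ 30 filtering.

## QC metrics

* human % = 100·mapped/total fragments; duplicate % = 100·(1 −
  after/before). Report output is rounded half-up to 2 decimals; raw
  values stay on the dataclass. Zero denominators yield None, not a crash.
* FOLD80 = mean depth / 20th percentile of per-base depth, with the
  percentile computed by linear interpolation between order statistics —
  stated explicitly because small arrays make the convention visible. A
  zero 20th percentile reports +inf with a warning.
* Genotypability is approximated as the fraction of target bases with
  depth ≥ 4 (a depth-threshold stand-in for full callable-locus logic,
  whose mapping/base-quality components are out of scope).
* Ti/Tv uses biallelic SNVs only (transitions A↔G, C↔T); zero
  transversions yields NaN with a warning.

## Variant prioritization

Both arms treat frequency rules as *flags*, not hard filters: downstream
steps select on the flag. A variant with no reported frequency in any
database is rare-flagged — absence from databases is not evidence of
commonness, and truly novel alleles must survive. Multi-component ClinVar
labels ("Pathogenic/Likely pathogenic") are retained if any component is in
the retained set {pathogenic, likely pathogenic, conflicting, uncertain
significance, other}; "Benign/Likely benign" collapses to the benign
spectrum, which the annotated arm drops (unless HGMD DM/DM? rescues it) and
which disqualifies the predicted arm (a benign record *is* a reported
classification). The two arms are disjoint by construction. The five
predictors of the ≥3-damaging rule (SIFT, Polyphen2, MutationTaster,
MutationAssessor, FATHMM) are modelled as abstract calls; their scores are
inputs. Severity-based narrowing of the rare clinical subset is manual
curation in practice, so it is an optional caller-supplied gene lookup;
without one, the subset is labelled severity-unfiltered. The modifier scan
classifies an exonic missense variant as common only when some reported
frequency strictly exceeds 5% (a frequency exactly at the threshold is
rare).

The table generator's truth records are produced by an independent
transliteration of these rules inside `synthetic_data.variants` (it never
calls the prioritization module), so the fidelity tests are a genuine
dual-route check. The planted pair defaults mirror the canonical
compound-het pattern: one pathogenic/likely-pathogenic + DM allele at
1.5×10⁻⁵ and one benign-labelled + DM? allele at 0.03, both heterozygous in
one gene.

## Haplotype panel model and phase inference

The panel is a founder mosaic: `n_founders` (default 8) random founder
haplotypes over sites with per-site allele frequencies U(0.05, 0.5);
non-carrier haplotypes are Poisson-breakpoint mosaics over the non-anchor
founders. The anchor allele exists only on founder 0, and each carrier
copies founder 0 over an identity-by-descent segment whose one-sided
lengths are exponential with scale `region_span/recomb_rate` — the
standard decay of haplotype sharing around a shared ancestral allele,
without a coalescent. Defaults chosen once: 500 haplotypes, 120 sites over
20 kb, anchor frequency 0.03 (15 carriers), recomb_rate 0.2 (mean one-sided
segment 100 kb ≫ the region, appropriate for an allele whose carriers
demonstrably share a block tens of kb long). The query position falls in
the inter-site gap adjacent to the anchor — well inside the expected
block, which mirrors the real geometry where the missing variant sits
mid-block; in `trans` its allele is absent from the panel entirely, in
`cis` the site is added with the alternate allele on every carrier.

`find_anchor_block` grows the interval greedily from the anchor,
including a site while the fraction of carrier haplotypes matching the
carrier-modal allele is ≥ threshold (default 0.98) and stopping each
direction at the first failure. Because block membership is a per-site
property, this equals the maximal contiguous passing interval containing
the anchor, which the brute-force interval-enumeration oracle in the tests
verifies. Concordance is measured against the carrier-modal allele (not
the panel-major allele): the question is what the *carriers* co-inherit.
The concordance unit defaults to the haplotype; an individual-level mode
(an individual is concordant when all its carrier haplotypes match) is
available because "98% of individuals" and "98% of haplotypes" are both
defensible readings. Missing alleles never match the modal allele.

`infer_configuration` requires the sample to be heterozygous for both
variants (otherwise cis/trans is undefined and it refuses). With t the
threshold: spanning block and carrier-query-allele fraction ≤ 1−t ⇒ trans;
fraction ≥ t ⇒ cis; everything else indeterminate — symmetric bands avoid
an asymmetric bias. A query outside the panel region warns and returns
indeterminate. `frequency_cooccurrence` multiplies the two population
frequencies (linkage-equilibrium assumption) and labels products below
10⁻⁵ as supporting trans when both variants co-occur in one individual.

## Orchestration and determinism

`run_pipeline` composes the stages without transforming any number; stage
outputs are embedded verbatim in the report, stage errors are captured per
stage and independent stages still run, and absent inputs skip a stage
with a log entry. All generator randomness flows from explicit seeds
(`make_demo_dataset` spawns per-stage seeds from one master seed via
`SeedSequence`), and a fixed seed reproduces byte-identical SAM/VCF/JSON
outputs. Demo problem sizes (3 000 reads on a 60 kb reference, 300-variant
table, 200-haplotype panel) keep the full bundle under a second while
exercising every stage; the statistical suites use 10⁵ fragments, 50–100
replicates per condition and 500-haplotype panels, sizes at which the
binomial tolerances in the tests are decisive.

## Known limitations

* The damage simulator's uniform error model cannot probe reference-bias
  or quality-correlated artefacts.
* The mt estimator assumes a known, fixed contaminant allele table and a
  known error rate; misspecifying either biases c.
* Genotypability here is depth-only and will overstate callability on
  low-quality real data.
* The founder-mosaic panel has no demography, gene conversion or
  genotyping error; real-panel block discovery additionally confronts
  phasing switch errors the model does not produce.
* The X-contamination SE is a 20-block jackknife; its 2·SE intervals run
  ~1–2 points under nominal 95% coverage (SE estimation noise).
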