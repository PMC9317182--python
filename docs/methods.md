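# Methods

This document states the scientific model the package implements: the
curation rules and their rationale, the concordance and complexity
definitions, the survival statistics, the synthetic cohort generator, and
the numerical conventions. It is the authoritative description; module
docstrings summarize it.

## Conventions

- Coordinates are 1-based and inclusive on both ends (hg19 chromosome
  lengths), with bare chromosome names (`1`…`22`, `X`, `Y`). BED files are
  converted to/from this convention at the I/O boundary only.
- An interval's size is `end − start + 1`; the reciprocal overlap of two
  intervals is the overlap length divided by the *larger*-relative size,
  i.e. `min(overlap/size_a, overlap/size_b)`, so both calls must be mostly
  explained by the shared region.
- All tabular output round-trips byte-identically (floats serialized via
  `repr`), so reruns can be compared by digest.
- All randomness flows through `numpy.random.default_rng(seed)`; the cohort
  generator spawns one child generator per patient so patients are
  independent and insertion order is irrelevant.

## Curation

Raw OGM output mixes true somatic lesions with germline polymorphisms,
reference artifacts and redundant calls. Curation is a fixed sequence of
stages; every input call surfaces in exactly one non-tombstone output
record, carrying full provenance.

1. **Confidence prefilter.** Per-type minimum confidence, kept when the
   score is at least the threshold: insertion 0, deletion 0, inversion 0.7,
   duplication −1 (i.e. all pass), intra-chromosomal translocation 0.3,
   inter-chromosomal translocation 0.65; CNV 0.99. These reflect each
   caller sub-model's score calibration: inversion and translocation calls
   are artifact-prone and need stringent cuts, while deletion/insertion
   scores are already conservative.
2. **Size filter.** SVs below 100 Kb (exclusive) and CNVs of 500 Kb or less
   are removed; translocations are exempt (they have no meaningful size).
   Small events are dominated by germline copy-number polymorphism and by
   label-resolution noise.
3. **Region filters.** An SV whose breakpoint falls in a masked region
   (telomeric/peri-centromeric and otherwise unmappable sequence), or a CNV
   at least half covered by masked sequence, is removed. A CNV reciprocally
   overlapping a known-polymorphism catalog entry by at least 70% with the
   same sign is removed as germline.
4. **Segment merging.** Same-sign CNV calls on one chromosome separated by
   gaps of at most 500 Kb are merged transitively into one record spanning
   the union; coverage-based segmentation frequently splits one lesion into
   adjacent segments.
5. **SV/CNV deduplication.** The SV and CNV pipelines often call the same
   unbalanced lesion. A CNV gain reciprocally overlapping a duplication, or
   a CNV loss overlapping a deletion, by at least 50%, is one abnormality;
   the surviving record keeps the SV coordinates (label-level resolution
   beats coverage-level). A CNV loss whose boundaries are bracketed within
   500 Kb per side by an intra-chromosomal translocation call is likewise
   absorbed; if that translocation spans at least 5 Mb it is re-labeled a
   deletion, since the SV caller reports large interstitial deletions in
   that form. The absorbed CNV remains as a `deduplicated` tombstone
   pointing at its survivor.
6. **Translocation artifact flag.** A translocation with at most 10 mapped
   labels on either partner, or raw alignment confidence below 10 on either
   side, is flagged (retained but not countable). Supporting-molecule
   counts are deliberately not used: validated rearrangements can rest on
   very few molecules, so that signal does not separate artifacts.
7. **Targeted rescue.** Calls discarded only by the confidence or size
   filters can be re-admitted under explicitly more permissive thresholds
   when they land on an independently known aberration for the same
   patient — mirroring how a reviewer relaxes stringency at known loci.
   The permissive configuration must be at most as strict as the default
   in every parameter, and artifact-like translocations are never rescued.
8. **Chromothripsis.** A (patient, chromosome) pair is flagged when it
   carries at least 10 SV breakpoints and the ordered copy-state sequence
   (losses/gains with the normal state inserted in gaps) switches at least
   twice — clustered shattering with oscillating copy number. CNV segment
   boundaries are not counted as breakpoints.

## Concordance

The known-aberration inventory combines CBA, FISH and CMA records: CMA
coordinates take priority for unbalanced lesions (a FISH/CBA CNV
overlapping a same-sign CMA entry in the same patient is the same lesion);
balanced rearrangements and "add" entries (additional material at a named
band, one known breakpoint) come from the karyotype.

Matching is deliberately tolerant because the techniques see one lesion at
very different resolutions. A known CNV matches a curated record of the
same sign when reciprocal overlap is at least 0.25 **or** both boundaries
agree within 5 Mb. A known translocation matches when each of its
breakpoints is hit by a curated breakpoint on the right chromosome within
10 Mb (band-level tolerance); an "add" needs its single breakpoint hit.
Known inversions also accept large intra-chromosomal translocation calls.
Each known entry takes its best-scoring candidate (highest overlap, then
smallest boundary difference, then lexicographic id, for determinism).

Unmatched entries get one reason, in fixed precedence: breakpoints within
1 Mb of a centromeric/telomeric annotation → `centromeric_telomeric`;
interval at least half masked → `masked_region`; clone fraction below 0.20
→ `sensitivity`; CNV under 150 Kb on a chromothripsis chromosome →
`small_within_chromothripsis`; else `unknown`.

Translocation calls that confirm nothing known are classified with
precedence real (matches a known rearrangement) > potentially real (a
breakpoint at the limit of a known CNV/CMA segment) > false positive
(externally invalidated) > potential false positive (artifact-flagged and
unsupported); unflagged, uninvalidated calls default to real, since
genome-wide techniques systematically under-ascertain balanced events.

## Complexity

A patient's complexity count is the number of countable curated records
(kept or rescued; tombstones, artifacts and filtered calls do not count).
By OGM, complex (C-OGM) means at least 10 abnormalities. By CBA or CMA,
counts bin into low (0–2), intermediate (3–4) and high (≥ 5). Agreement
between C-OGM and "high by CBA and/or CMA" is a 2×2 cross-classification
scored by Cohen's kappa with a one-sided large-sample z test of kappa = 0
(null standard error `sqrt(pe / (n (1 − pe)))`).

Complex and non-complex groups are compared covariate by covariate:
categorical covariates (TP53 lesion, chromothripsis, conventional high
complexity) by Pearson chi-square when every expected count is at least 5
and by the exact Fisher test otherwise; count covariates by the
Mann–Whitney U test. Missing values shrink the reported denominators.

## Survival

TTFT is right-censored at last follow-up; patients treated before genetic
sampling are excluded. Kaplan–Meier estimation, the log-rank test and
Harrell's C-index are delegated to lifelines, with conventions fixed here:
events precede censorings at tied times; the median is the smallest time
with survival ≤ 0.5 (undefined if never reached); the C-index is oriented
so a higher abnormality count predicting earlier treatment scores above
0.5 (pairs with tied event times are not comparable; an event tied with a
censoring is).

## Statistics

Cohen's kappa, chi-square (no continuity correction) and expected counts
are authored directly. The two-sided exact Fisher test is an authored
integer hypergeometric enumeration — summing the probability of every
table with the observed margins at most as probable as the observed one —
with results cached per margin set; this was written in-house because the
full exhaustive verification sweep (every 2×2 table with n ≤ 40) must run
in seconds, which the general-purpose scipy implementation does not do,
and exact integer comparison avoids tie-tolerance heuristics. scipy
remains the independent test oracle, and supplies the conditional-MLE odds
ratio. Spearman and Mann–Whitney delegate to scipy (exact Mann–Whitney p
for small tie-free samples, normal approximation with tie correction
otherwise).

## Synthetic cohort generator

The generator produces a CLL-like cohort under a fully specified model,
with the default configuration representing a 42-patient study population
(18 complex-karyotype patients). Per patient:

- **Truth.** The number of true abnormalities is zero-truncated negative
  binomial (mean 4 non-CK, 20 CK; dispersion 3). Classic CLL lesions are
  drawn first with literature-scale frequencies (del(13q14) 0.60, trisomy
  12 0.19, del(11q22) 0.29, del(17p13) 0.17 — the last defining the TP53
  lesion); remaining abnormalities draw classes with fixed weights and
  log-uniform sizes, placed in mappable, non-polymorphic windows. CK
  patients may receive a chromothripsis cluster (oscillating losses plus
  clustered intra-chromosomal translocations on one chromosome). Each
  abnormality carries a clone fraction drawn log-uniformly from
  [0.02, 1].
- **OGM observation.** Detection probability is 0 below a clone-fraction
  floor (5% SV, 10% CNV) and ramps linearly to 1 at 20%. Observed calls
  get coordinate jitter, plausible confidence/label/molecule support, and
  pass through noise channels: CNV segmentation (probability 0.3, gaps
  below the merge distance so curation recovers the span exactly), dual
  SV+CNV calls (probability 0.2), polymorphism CNVs copied from the same
  catalog the curation filter uses, and artifact translocations
  (Poisson, mean 1.2/patient) that always carry low label or raw-confidence
  support. Every emitted call id maps to a truth id, `artifact:*` or
  `polymorphism:*` in the truth set.
- **Conventional techniques.** CBA reports balanced rearrangements and
  large unbalanced lesions with band-level rounding and detection scaling
  with clone fraction; CMA reports unbalanced lesions near-exactly when the
  clone fraction is at least 20%; FISH reports the classic panel loci down
  to 3%.
- **Clinical.** TTFT is exponential with median 43 months for non-complex
  truth and hazard ratio 3 for complex; follow-up is finite, so observed
  treatment is censored accordingly; a small fraction of patients is
  pre-treated.

`evaluate_recovery` scores pipeline output against truth: per-patient count
error, risk-class confusion and recovery (overall and among fully clonal
patients at clone fraction ≥ 0.3), detection rate by clone-fraction bin,
and artifact-filter precision/recall. By construction, fully clonal
patients are recoverable exactly: artifacts always violate the support
thresholds, polymorphisms match the filter catalog, segments re-merge, and
dual calls deduplicate — so recovery failures indicate pipeline defects,
not generator noise.

## Limitations

- The generator is a model of the analysis problem, not of raw molecule
  imaging: calibration (confidence distributions, artifact structure) is
  plausible rather than fitted to instrument data.
- Masked regions default to fixed telomeric/peri-centromeric flanks rather
  than a curated unmappable-region catalog.
- Matching tolerances (0.25 reciprocal overlap, 5/10 Mb) encode band-level
  agreement and are configurable but not learned.
- The survival model has proportional hazards by construction; the C-index
  and log-rank behavior under non-proportional hazards is untested.
- Chromothripsis detection is a two-signal heuristic (breakpoint count and
  copy-state oscillation), not a formal statistical test of random joining.
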