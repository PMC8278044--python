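# Methods

## The Likelihood of Diagnosis

`lodiag` treats diagnosability as a product of two ingredients measured from
the data themselves:

* **Preservation potential (PP).**  Each skeletal element's PP is the share
  of all recorded element occurrences it contributes, tallied over *every*
  specimen — named species, unnamed-but-informative specimens, and
  indeterminate material (a configurable filter can restrict to species-rank
  records).  A specimen contributes at most once per element regardless of
  recorded multiplicity, because the underlying observations are
  presence/absence.  PP is a pure proportion: it always sums to 1, is scale
  invariant, and elements never observed keep PP = 0 so their LoD terms
  vanish rather than erroring.  No taphonomic model is implied — PP describes
  *that* elements preserve differentially, not why.

* **Character weight (Ch).**  Formal diagnoses are atomized into characters,
  each targeting one element.  A standalone autapomorphy weighs 1; each
  member of a k-character unique combination weighs 1/k, the combination as a
  whole being equivalent to one autapomorphy (a four-member combination gives
  each member 25%).  Diagnoses published in 1980 or earlier are discarded
  entirely (autapomorphies were generally not explicit before then;
  "post-1980" is implemented as publication year ≥ 1981) and the species is
  flagged as lacking a quantifiable diagnosis.  Characters naming whole body
  partitions, integument, multi-element fenestrae or multi-element
  associations cannot be assigned to a single element and are removed, each
  removal logged with its rule.

  When a combination loses members to exclusion, the denominator k remains
  the *pre-exclusion* size and the excluded shares are dropped, not
  redistributed: the excluded information cannot be attributed to an element,
  and renormalizing would silently inflate the survivors.  A
  `combination_denominator="post_exclusion"` switch provides the alternative
  reading (the sources do not settle which was intended).

* **LoD(s) = Σ Ch_e × PP_e.**  High when many characters sit on commonly
  preserved bones.  Zero-LoD or unquantifiable species are excluded from LoD
  summaries but still count toward abundance, and every species lands in
  exactly one of: usable-LoD table, zero-LoD report, no-diagnosis report.

Group-level diagnosability is the mean of log LoD over constituent species
(log base 10 by default; the base only rescales comparisons and the package's
base-change identity is tested).  Logging precedes averaging so single
well-diagnosed outliers do not dominate.  Region summaries report, per
skeletal region, the percentage of element occurrences and of pooled
character weight (radial-plot tables), plus "skeletal coverage" — the
fraction of schema elements carrying any character weight, with the whole
schema as denominator by default (`"observed"` restricts to elements seen in
the group).

## Abundance proxies

Species MNI uses the classical zooarchaeological rule: the most duplicated
element, honouring within-specimen multiplicities when recorded (a bonebed
slab with five femora implies five individuals), otherwise presence per
specimen.  This equals the true minimum over all assignments of elements to
individuals, and the test suite checks it against an exhaustive enumeration
oracle on small instances.

Group MNI sums constituent species MNIs (diagnosable or not) plus
indeterminate material.  Indeterminate specimen records carry no
spatio-temporal information, so their contribution is resolved by taxon name
in subgroup mode and from higher-rank occurrence rows (their individual
counts) in formation and stage modes.  Occurrence-based proxies — number of
occurrences, individuals, unique localities (collections), and the ratios
individuals/locality, individuals/species, species/locality, MNI/species —
are tallied over every occurrence row assigned to the group, higher-rank
records included; species richness counts valid species only.  Missing
individual counts in PBDB-style input default to 1.  Ratios with a zero
denominator are reported as NaN, never as 0.

## Binning

Subgroups partition species; a species occurring in several formations is
duplicated into each (and its full MNI counts in each, consistent with the
multi-stage rule).  Formation mode can restrict to the N most species-rich
formations (default 5; ties broken lexicographically, so binning is
deterministic).  Stage bins use half-open intervals [younger, older) Ma, so a
point age on a boundary falls in exactly one stage, while a species whose
range spans several stages is included in each stage it could occupy.  The
packaged Mesozoic stage table (Induan–Maastrichtian, ICS-style bounds) is a
replaceable data file.

## Regression

Comparisons are linear fits of (mean log) LoD against each log-transformed
proxy, by maximum likelihood: iid errors for taxonomic and formation
comparisons (equivalent to OLS), and AR(1)-correlated errors for stage-level
time series to avoid overstating significance under temporal autocorrelation.
The AR(1) likelihood is profiled: for fixed ρ the GLS estimate and
concentrated σ² are closed-form via the standard whitening transform (first
observation scaled by √(1−ρ²), the rest differenced), and ρ is maximized
numerically over (−0.99, 0.99).  Adjacent bins are one AR(1) step apart
regardless of stage duration (order-based lags).  ML rather than REML is used
throughout so the model-versus-null likelihood difference is valid for

```
pseudo-R² = 1 − exp(−(2/n)(ℓ_model − ℓ_null))
```

with the intercept-only null fitted under the same correlation structure and
transformation.  A Nagelkerke-style rescaling (dividing by the maximum
attainable value) is available by flag but not the default.  Standard errors
use the n−2 residual-variance denominator, so with iid errors slope, t and
two-tailed p (t distribution, n−2 df) reproduce the textbook OLS closed forms
exactly — the suite checks this to 1e−8 and cross-checks log-likelihoods
against an independent OLS implementation.

Non-positive values are deleted pairwise before log transforms, with counts
logged: a zero-abundance bin has no defined log abundance, and zero-LoD
species are definitionally excluded from LoD comparisons.  Group responses
(mean log LoD) are already on a log scale and are not logged again.  No
multiple-testing correction is applied.

## The synthetic fossil record

The generator states an explicit world and emits the exact CSV dialects the
readers consume:

* ~60 species (configurable) in 4 subgroups and 8 formations over a
  Mesozoic-style stage table; species ranges of 2–8 Ma placed uniformly in
  230–70 Ma.
* Per-element relative preservability follows a theropod-like profile
  (femur, tibia, caudal vertebrae, teeth, metatarsals commonest; sternum,
  furcula, carpals rarest); per-specimen element presence is Bernoulli with
  probability proportional to it, scaled so the commonest element appears in
  60% of specimens.  Empirical PP therefore converges to the configured
  proportions (tested at ~2000 specimens, tolerance ±0.05).
* Characters per species are Poisson with mean 4, placed on elements
  uniformly (independently of preservability by default; a flag couples
  them, and per-region multipliers can bias placement).  A quarter of
  characters arrive inside unique combinations of 2–4 members.  5% of
  species draw a pre-1981 publication year, exercising the exclusion filter.
* Latent abundance is λ = 6 · (LoD/0.1)^β · exp(ε), ε ~ N(0, 0.5²):
  `coupling_beta` is directly the true slope of log-abundance on log-LoD,
  and β = 0 is a null world.  The specimen count is Poisson(λ); species
  drawing zero specimens are unobserved and appear in no table (the manifest
  still records them).  The baseline of ~6 expected individuals per species
  at the reference LoD of 0.1 represents a moderately well-sampled record —
  real theropod species are typically known from even fewer specimens.
* Every specimen yields one single-individual occurrence at a locality
  within one of its species' formations; ~10% extra indeterminate
  higher-rank specimens and occurrences are added.

All randomness flows through one seeded `numpy` generator; a fixed seed
reproduces every table byte for byte, and replicate suites derive
per-replicate seeds from a single `SeedSequence` recorded in a manifest.

What a green test on this world does *not* establish: the generator draws
specimens independently and uniformly in time and space, so it cannot expose
biases from facies, lagerstätten, collection effort, body size or taxonomic
practice; nor does it model the manual literature cross-referencing that
curated real MNIs.

## Calibration results and known limitations

* **Type-I error.**  Under the null world (β = 0, 60 species), the
  species-level LoD ~ MNI test rejects at α = 0.05 in about 5% of 1000
  replicates (the suite asserts the rate lies in [0.03, 0.08]).
* **Parameter recovery and proxy attenuation.**  With β = 0.5 and 100
  species, regressing log individual counts on log LoD recovers a mean slope
  of ≈ 0.45, about 10% below truth.  This is finite-abundance estimator
  bias, not an implementation defect: species drawing zero specimens are
  unobservable (a selection correlated with the abundance residual), and the
  log of a small Poisson count is a biased reading of log λ.  The bias
  shrinks as baseline abundance grows, and at the package's realistic
  default (~6 individuals per species) the recovery suite documents the
  residual attenuation rather than hiding it.  MNI attenuates further still
  (mean slope ≈ 0.41): as a floor-bounded minimum estimate driven by one
  element, it compresses genuine abundance variation, and any LoD–abundance
  effect measured through MNI should be read as a lower bound.
* LoD inherits the record's own biases: PP is estimated from the same
  specimens whose identification it is meant to explain, and species
  identified "by general similarity" rather than by autapomorphy decouple
  abundance from formal diagnosability.  The pipeline quantifies the
  relationship; it cannot by itself prove the direction of causation.
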