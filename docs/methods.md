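# Methods note

This note records the exact model implemented by `idcard`, the parameter
defaults and why they were chosen, what the synthetic data generator does and
does not model, and the numerical choices that make results reproducible.
The method follows Wang *et al.* (2025), *Food Science & Nutrition*
13:e70163 ("digital identity card" for CRP/XCRP).

## 1. Data model

A **feature table** is one sample's list of ion features
(Rt [min], m/z [Da], intensity [arbitrary counts]), stored as parallel
float64 arrays (`FeatureTable`). Validation: Rt > 0, m/z > 0, intensity ≥ 0,
roles `sample` / `blank` / `reference`. CSV I/O uses columns
`rt_min, mz, intensity` (remappable) and is bit-exact on round trip
(repr-precision writes, `float_precision="round_trip"` reads).

**Matching predicate.** Ions *a*, *b* match iff

```
|Rt_a − Rt_b| ≤ ΔRt + ε   and   |mz_a − mz_b| ≤ Δmz + ε ,   ε = 1e-9
```

with defaults ΔRt = 0.05 min, Δmz = 0.05 Da (`ToleranceSpec`). The
threshold is *inclusive*: the published multi-match example has sample ions
at 258.08 and 258.18 Da matching a card ion at 258.13 Da, i.e. deviations of
exactly 0.05 Da. In binary floating point `258.13 − 258.08` evaluates to
slightly *more* than 0.05, so a naive `≤` would reject a case the method
defines as a match; the ε guard makes the predicate agree with decimal
arithmetic for printed-precision data while being far too small (ppm-scale
Rt, sub-ppm m/z) to admit any physically distinct ion. The ε is part of the
predicate's definition and is used identically in library code and test
oracles. Intensity never participates in matching.

## 2. Card construction

Given ≥ 2 batches per origin and ≥ 2 origins (`build_cards`):

1. **Rt window** [1.00, 26.00] min, inclusive (chromatographic dead time and
   column-wash tail are uninformative).
2. **Blank deduction**: drop every sample ion matching *any* ion in the
   union of blank runs. Idempotent by construction.
3. **Shared-ion extraction** (`extract_shared_ions`): the first batch is the
   anchor; an anchor ion is kept iff every other batch (or ≥ `quorum`
   batches) contains a matching ion. The representative keeps the anchor's
   coordinates; its intensity is the mean of the anchor's intensity and, per
   matching batch, the intensity of the closest match (smallest |Δm/z|, ties
   by |ΔRt|). The mean is summed over value-sorted contributions so batch
   order cannot perturb the float result.
4. **Deduplication** (`dedup_similar_ions`): greedy scan in descending
   intensity; an ion is dropped if it matches an already-kept ion.
5. **Unique-ion screening**, two strategies:
   - `shared_vs_shared` (traceability): remove ions matching any *other
     origin's shared set*;
   - `shared_vs_raw` (adulteration): remove ions matching *any raw ion of
     any contrast batch* — strictly more aggressive, needed when the classes
     share most of their chemistry.
6. **Top-N selection**: N most intense ions (default N = 100, as published);
   ties broken by m/z then Rt ascending. Cards with fewer than N ions keep
   what they have and MC uses the actual size as denominator.

Cards serialize to JSON with the preprocessing fingerprint (Rt window,
tolerances, blank policy, quorum, strategy) in metadata. Card files carry
**no timestamps**; run metadata lives in the CLI's `run_manifest.json` only,
so primary outputs are byte-identical across reruns. "Dynamic update" when
new batches arrive is a full rebuild — the pipeline is deterministic and
cheap (seconds at study scale).

## 3. Matching and decisions

`count_matched_pairs(card, sample)` counts **pairs**: each (card ion, sample
ion) combination within tolerance contributes one. One card ion matched by
two sample adducts yields two pairs, so

```
MC = 100 × pairs / card_size   [%]
```

can exceed 100 (published example: 109.00%). A `numerator_mode="unique"`
variant capping each card ion at one match is provided for sensitivity
analysis but the published pair-count mode is the default everywhere.

- **Traceability** (`trace_origin`): argmax-MC origin among ≥ 2 cards;
  tied maxima → status `ambiguous` (never silently broken); all-zero profile
  → `unclassifiable`. `margin` = best MC / runner-up MC.
- **Adulteration** (`detect_adulteration`): flag iff MC vs the adulterant
  card **strictly exceeds** the threshold (default 50%, the published
  recommendation). Both MCs are always reported.
- **Mixture study** (`mixture_series_experiment`): builds the two-class
  shared-vs-raw card pair, then for each mass proportion p blends one batch
  of each class (authentic intensities × (1−p), adulterant × p, fresh
  coordinate jitter, detection floor applied) and scores both MCs.

If a sample violates a card's recorded preprocessing fingerprint (e.g. ions
outside the build-time Rt window), matching proceeds but emits a
`PreprocessingMismatchWarning`.

## 4. Synthetic data generator

Real raw data for the original study are not deposited, so validation uses
corpora with planted ground truth (`generate_corpus`). Scope:

- **Common panel** (default 2,800 ions): genus-wide chemistry shared by all
  origins — what makes origins hard to distinguish.
- **Unique panels** (400 ions per origin): the origin-specific chemistry the
  cards should recover.
- **Batch noise** (1,200 ions per sample, never repeated across samples):
  one-off contaminants and misintegrated peaks. Modeling non-reproducible
  features per *batch* (rather than per origin) is deliberate: per-origin
  reproducible filler would, by definition, survive shared-ion extraction
  and screening and would be indistinguishable from unique-panel chemistry —
  there would be no ground truth to assert against.
- **Blank panel** (4,500 ions): solvent/matrix background, emitted as
  standalone blank tables and injected (300 ions) into every sample.

All planted ions live in distinct cells of an Rt × m/z grid with 0.15-unit
spacing — more than twice the matching tolerance — drawn globally without
replacement, so distinct planted ions can never tolerance-match even after
jitter and ground truth is unambiguous (infeasible panel sizes raise a
configuration error). Per sample, each panel ion survives with probability
1 − dropout (default 0.05), receives Gaussian coordinate jitter
(SD 0.01 min / 0.01 Da — well inside the 0.05 window), and gets intensity
`exp(N(10, 1.5²)) × exp(N(0, 0.3²))` (ion base level × per-batch factor);
ions below the **detection floor** (default 5,000 ≈ a quarter of the median
base intensity) vanish. The floor is the mechanism that makes a minor
mixture component lose part of its fingerprint — matching the published
observation that a 5% adulterant is detectable but scores well below its
pure-material MC. Defaults reproduce the study scale: 5 origins × 6 batches,
~3,000–4,500 ions per sample, blanks of ~3,500–4,000 ions. Everything is
driven by one seeded `numpy` generator; corpora are bit-identical per seed.

Not modeled: chromatographic peak shapes, Rt drift correlated along the
gradient, isotope/adduct structure (multi-match is exercised via explicit
fixtures instead), inter-ion intensity correlations.

## 5. Numerical choices

- Tolerance joins sort by m/z and use `searchsorted` candidate windows
  (padded by 2ε) followed by the exact predicate, bit-identical to the naive
  double loop (property-tested) at O((n+m) log m).
- All tie-breaks are total and documented: dedup order
  (−intensity, m/z, Rt); closest match (|Δm/z|, then |ΔRt|, then index);
  top-N ties (m/z, Rt); profile ordering (−MC, label).
- MC is reported to two decimals (`round(,2)`) only at presentation
  boundaries; internal comparisons use full precision.

## 6. Known limitations

- **Shared-vs-shared leakage.** With per-batch dropout, a common ion absent
  from every batch of *one* other origin escapes shared-vs-shared screening;
  at study scale a few such ions per card produce cross-MCs of 2–4%. This is
  inherent to the published method and is precisely why the original authors
  switch to shared-vs-raw screening for adulteration, where the contrast
  class overlaps heavily. The package mirrors that split (traceability:
  shared; adulteration: raw).
- MC is a descriptive match statistic, not a calibrated probability; the 50%
  adulteration threshold is the published heuristic, exposed as a parameter.
- The anchor-batch rule makes shared-set coordinates depend on which batch
  is listed first (ion *identity* does not); card contents are invariant to
  the order of the remaining batches.
- Pair-count MC rewards adduct-rich samples; the `unique` numerator mode is
  provided to quantify that effect.
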