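# Methods

This note records the models, conventions and design choices behind
`mrharmony`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Diagnosis–protocol overlap

**Elements.** The unit element of every diagnosis set is the *code
combination*: one exam's canonicalized, deduplicated, sorted tuple of ICD-10
codes (`CodeSetElement`). Two exams contribute the same element exactly when
their code sets are identical. A per-code granularity (each individual code
an element) is available behind `granularity="code"` as a documented
variant; the default is combinations.

**Canonicalization.** Codes are uppercased, stripped, and a dot is inserted
after the third character of longer undotted codes ("M545" → "M54.5"). The
canonical shape is one uppercase letter, two digits, optionally "." plus 1–4
alphanumerics. Codes are otherwise treated as opaque strings: no validation
against an official ICD-10 catalog is attempted, because catalog versions
drift across years and jurisdictions and the analysis never needs code
semantics.

**Filtering.** "Performed more than five times" is implemented as
*retain exam count ≥ 6* (`min_count`, configurable). Exams without any coded
diagnosis are kept by I/O but excluded — with a logged count — by the
overlap stage, since every statistic assumes at least one code per exam.
Label statistics are computed over *all* region exams with nonempty codes,
before the protocol-frequency filter; the filter shapes only the matrix.
Matrix rows are ordered by descending exam count with lexicographic
tie-break (an `alpha` policy is available); the ordering is presentation
only and does not affect any coefficient.

**Complement overlap.** The literal set complement Aᶜ = U \ A is disjoint
from A, so oc(A, Aᶜ) would be identically zero and carry no information.
The implemented quantity is oc between A and the union of the *other*
protocols' element sets — the reading under which the coefficient measures
how much of a protocol's diagnosis set recurs anywhere else, which is the
question the analysis asks. It is 0 exactly when the protocol's diagnoses
are unique to it, and undefined (a distinguished `None`, never silently 0
or 1) for a single-protocol dataset.

**Rounding.** All internal arithmetic is float at full precision; values are
rounded to two decimals only at the output boundary (matrix CSV, display
fields).

## Sequence-name standardization

Standardized names are a pure function of acquisition parameters; the
user-given name is never consulted. The rule engine evaluates an ordered
list of conjunctive conditions (numeric ranges, categorical any-of, boolean
flags) and returns the first matching rule's weighting token; a terminal
catch-all guarantees a token. The default table (also shipped as
`rules/default.yaml`) is a conventional MR-contrast heuristic:

| rule | condition | token |
|---|---|---|
| diffusion | max b-value > 50 s/mm² | DWI |
| flair | IR, TI ∈ [1800, 2800] ms | FLAIR |
| stir | IR, TI ∈ [120, 300] ms | STIR |
| t1-spin-echo | SE/TSE, TR < 800 ms, TE < 30 ms | T1 |
| t2 | TR > 2000 ms, TE > 80 ms | T2 |
| pd | TR > 2000 ms, TE < 30 ms | PD |
| t1-gradient-echo | GRE/bSSFP, flip > 50°, TR < 800 ms | T1 |
| catch-all | — | OTHER |

Ordering is load-bearing: diffusion precedes inversion recovery precedes
relaxation-based rules, so a diffusion EPI with long TR/TE is DWI, not T2,
and a FLAIR with long TR is FLAIR, not T2. The TI windows are wide enough to
cover both 1.5 T and 3 T conventions; field-strength-specific windows can be
supplied via a custom rule file. Fat-saturation and contrast markers are
suffix tokens rather than weighting modifiers, keeping the classifier
single-purpose.

Token assembly order is: weighting, technique family, orientation (omitted
when UNKNOWN), dimensionality, `FS`, `C+` — e.g. `"T1 SE SAG 2D"`,
`"FLAIR TSE TRA 2D FS"`. Dimensionality and contrast tokens can be disabled
per rule file (`options:`), since conventions differ on whether 3D variants
or contrast phases deserve distinct standardized names.

The rule thresholds themselves are a design choice of this package: they
encode textbook MR contrast conventions, and any site can replace them
wholesale with its own YAML file without touching code.

## Tree comparison and the chi-square construction

Scanners are compared against a reference scanner (an all-pairs mode
exists behind a flag) by the overlap coefficient of their name sets at the
raw, standardized and protocol levels. Per-scanner unique-name counts are
averaged with display rounding half away from zero (310/3 → 103).

The variability comparison is a chi-square test of homogeneity on the 2×K
table whose rows are the per-scanner unique *raw* and *standardized* name
counts (columns: scanners, expected counts from the margins, df = K − 1,
no continuity correction). Caveats: the "observations" are set sizes, not
independent event counts, so the test is a descriptive index of
proportionality rather than a calibrated significance test; on the published
three-scanner count table ([231, 200, 196] vs [104, 98, 89]) it yields a
statistic near 0.29 (p ≈ 0.87), i.e. the count *profiles* across scanners
are nearly proportional even though standardization halves their level. A
per-pair comparison of overlap coefficients would be an alternative
construction; it is noted here but not implemented, because no test
construction for it is standard.

## Synthetic data

The generator emulates the statistical structure the analyses consume —
never clinical semantics (which diagnosis truly warrants which protocol is
out of scope).

**Exam logs.** Per region: protocol frequencies follow a truncated power law
(exponent 1.2) anchored at the configured range endpoints and balanced to
the exact exam total; per-exam code-set size is drawn i.i.d. from the
configured cardinality distribution (defaults {1: 0.9, 2: 0.1} for spine,
mean 1.1, and {1: 0.8, 2: 0.2} for brain/head, mean 1.2); code popularity is
Zipf-like with exponent 1.2, so single-code occurrence spans roughly unity
to a few hundred at spine scale. The realized number of *distinct* codes and
the label diversity are emergent, not calibrated; they land near but not at
the study's values.

**Planted overlaps.** For each planted pair the element sets are built
explicitly: every planted exam receives its own distinct code combination,
with exactly `target · min(|A|,|B|)` combinations shared between the pair.
To make that product integral for any rational target, the smaller
partner's exam count is adjusted to a multiple of the target's reduced
denominator (the difference is redistributed to non-planted protocols,
preserving the exam total and frequency range). Recovery of the planted
coefficient through the full pipeline is therefore an *exact* equality
check, not a statistical one; an unrealizable target (denominator larger
than the feasible set size) is rejected with the offending pair named. The
study-scale config plants 0.5 on a cervical protocol pair and 1/6 (which
prints as 0.17) on a lumbar pair.

**Trees.** A shared core of parameter tuples (default 200) is reused on
every scanner; each site adds its own tuples at
`site_specific_sequence_rate`, and each scanner independently drops core
tuples at half that rate — so both rates at zero give identical trees. Each
tuple owns a pool of three raw spellings, globally disjoint across tuples;
a scanner uses the canonical spelling unless the synonym noise fires.
Disjoint pools make raw names *refine* parameter tuples (equal raw name ⇒
equal parameters), so standardization can only merge names, never split
them, and per-scanner unique-raw-name counts equal pool sizes (every pool
tuple is used by at least one protocol). Two determinisms are forced for
test sharpness: the first two core tuples share categorical parameters (so
standardization strictly reduces counts on every scanner), and when the
synonym rate is positive the first core tuple is deliberately spelled
differently on scanner 1 than elsewhere (so raw overlap is strictly below
standardized overlap on shared-core configurations).

The directional phenomenon — oc(standardized) ≥ oc(raw) across scanner
pairs — is not a theorem for arbitrary inputs (a contrived merge pattern
can violate it); it holds by wide margins on this generator's outputs and
is asserted there.

**Randomness.** One root seed; every component (vocabulary, exam draws,
shuffling, core tuples, site extras, per-scanner choices) derives its own
`numpy` seed stream from `[seed, component_id, index]`, so adding a
component never perturbs the others, and identical configurations produce
byte-identical serialized outputs.

## Problem sizes

The default test and acceptance runs use the study-scale configuration
(976 exams over two regions, 3 scanners, 200 core tuples, ~100 protocols
per scanner) plus smaller 6-protocol/120-exam configurations across 20
seeds for planted-overlap recovery; the whole suite completes in a few
seconds on one core. These sizes were chosen as the smallest that exercise
every envelope the generator promises.

## What passing tests do and do not show

The synthetic data reproduces marginal shapes (cardinality, skew, planted
overlap, synonym structure), not the joint diagnosis–protocol semantics of
real practice data. Passing tests therefore validate the *computations* —
formulas, filters, rule engine, report assembly — and the generator's
envelopes; they do not certify that real exam logs would yield any
particular overlap values. The published headline matrices from the private
study data (complement ranges 0.14–0.56 and 0.04–0.57; tree oc 0.81/0.86 →
0.93) are not reproducible without that data; what the package reproduces is
the arithmetic on the published count tables and the qualitative
standardization phenomenon.

## Known limitations

- ICD-10 codes are opaque strings; no catalog validation or hierarchy.
- Body-region matching is exact lowercase string equality; no anatomical
  ontology.
- The chi-square construction is descriptive (see above); it does not
  reproduce a significance claim for standardization.
- The rule table covers the common contrast classes only; exotic sequences
  fall to OTHER by design.
- No DICOM networking, HL7/FHIR or RIS connectivity; exam logs and trees
  enter as CSV/JSON.
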