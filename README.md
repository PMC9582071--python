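# mrharmony

Overlap analytics for MRI exam logs and scanner protocol trees.

Selecting the right MRI protocol for an ordered exam ("protocoling") is a
time-consuming radiologist task and a target for automation. Two data
questions decide whether automation can work:

1. **How much does the admitting diagnosis tell you about the protocol?**
   If the ICD-10-coded admitting diagnoses of two protocols overlap heavily,
   the diagnosis alone cannot separate them.
2. **How comparable are the protocol trees of different scanners?** If every
   scanner names its sequences differently, a model trained at one scanner
   does not transfer — and much of the apparent difference may be naming,
   not content.

`mrharmony` quantifies both, for radiology-informatics researchers and
physicists who curate protocol trees.

## The statistics

For finite sets *A*, *B* the package uses the Jaccard index and the
(Szymkiewicz–Simpson) overlap coefficient

    J(A, B)  = |A ∩ B| / |A ∪ B|
    oc(A, B) = |A ∩ B| / min(|A|, |B|)

with *J ≤ oc* always, and *oc = 1* whenever one set contains the other —
which makes *oc* the better-behaved choice for the small, unevenly sized
sets that arise here.

For the diagnosis analysis, the elements of *A* are **code combinations**:
each exam contributes its whole (canonicalized, deduplicated) ICD-10 code
set as one element to its protocol's set. Protocols performed fewer than six
times are dropped. Besides the pairwise matrix, each protocol gets a
**complement overlap coefficient** — *oc* between its element set and the
union of every other protocol's elements — which is 0 exactly when its
diagnoses are unique to it. Label **cardinality** (mean codes/exam),
**density** (cardinality / number of unique codes) and **diversity**
(distinct code sets) summarize the annotation.

For the tree analysis, scanners are compared by the *oc* of their name sets
at three levels: raw sequence names, **standardized** sequence names, and
protocol names. Standardized names are rebuilt purely from acquisition
parameters (TR, TE, TI, technique, orientation, b-values, ...) by an
ordered, YAML-configurable rule table (`rules/default.yaml`) — identical
acquisitions get identical names regardless of how a site spelled them, so
the gap between raw-level and standardized-level *oc* isolates naming
inconsistency. A chi-square homogeneity test compares raw vs standardized
unique-name counts across scanners.

Because real exam logs are private, `mrharmony` ships a seeded synthetic
generator that emulates their statistical shape (cardinality ≈ 1.1–1.2,
skewed code popularity and protocol frequencies, synonym-noised trees with a
shared parameter core) and can *plant* exact pairwise overlaps for
validation.

## Worked example

```bash
mrharmony simulate --config configs/toy.yaml --seed 7 \
    --out-exams exams.csv --out-trees trees.json
mrharmony dx-overlap --exams exams.csv --body-region spine \
    --out-matrix matrix.csv --out-stats stats.json
mrharmony compare-trees --trees trees.json --reference scanner1 \
    --out report.json
```

`matrix.csv` (toy run above):

```
protocol,SPINE 00,TOY/A,SPINE 01,TOY/B,complement
SPINE 00,1.00,0.40,0.29,0.50,0.50
TOY/A,0.40,1.00,0.71,0.50,0.62
SPINE 01,0.29,0.71,1.00,0.43,0.86
TOY/B,0.50,0.50,0.43,1.00,0.75
```

The cell `TOY/A × TOY/B = 0.50` recovers the overlap planted by the toy
configuration exactly: half of the smaller protocol's admitting-diagnosis
combinations also occur under the other protocol, so the diagnosis alone
cannot separate the pair. The `complement` column shows how much of each
protocol's diagnosis set recurs anywhere else. `stats.json` reports
cardinality 1.12 (≈1.1 codes per exam), 17 unique codes, diversity 23.

`report.json` shows the naming effect across scanners:

```
scanner2 vs scanner1:  oc raw 0.40   standardized 1.00   protocol 0.90
scanner3 vs scanner1:  oc raw 0.38   standardized 0.81   protocol 0.83
```

Raw sequence-name overlap is low (0.38–0.40), but after parameter-based
standardization it rises to 0.81–1.00: most of the apparent heterogeneity
was spelling, not sequence content. Mean unique names per scanner drop from
32 (raw) to 23 (standardized).

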