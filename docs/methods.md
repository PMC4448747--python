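# Methods

## Data model

The atomic unit is the activity record: one measured compound–target
interaction from one assay, with the attributes a ChEMBL-style flat export
carries — compound, target and assay identifiers, target type and
organism, assay relationship type (single-character code; `D` = direct),
assay confidence score (integer 0–9; 9 = direct single-protein
assignment), measurement type (`Ki`, `IC50`, or other), measurement
relation (`=`, `>`, `<`, `~`), a free-text activity comment, a numeric
value in nM, and a release year. Identifiers are opaque strings; compound
identity is the identifier, with no structure-based canonicalization or
deduplication — a database entry is a compound, as in the underlying
resources.

Release dates are reduced to calendar-year granularity. All statistics
here are annual; input files may carry full dates, which the reader
truncates to the year. Dates that cannot be resolved to a year inside a
configured plausible range (default 1900–current year) are rejected with a
counted reason rather than guessed at.

Reading is strict but total: every input row is either retained or
counted under a named rejection reason (missing identifier, malformed or
out-of-range confidence score / year / value, byte-identical duplicate),
so `rows read = retained + rejected` holds exactly. Byte-identical
duplicates are removed at load because they would inflate activity-record
growth counts; near-duplicates (same compound/target/assay, different
values) are retained, which is harmless downstream because promiscuity
counts distinct targets, not records.

## Confidence tiers

Two record tiers bracket data quality:

- **high**: relationship type `D` ∧ confidence score 9 ∧ target type
  `SINGLE PROTEIN` ∧ organism `Homo sapiens` ∧ measurement type ∈ {Ki,
  IC50} ∧ relation `=` ∧ value present ∧ comment free of inactivity
  phrases;
- **low**: target type `SINGLE PROTEIN` ∧ organism `Homo sapiens` only.

Decisions taken where the rules are genuinely open:

- Comment screening uses case-insensitive *containment* of the phrases
  "inactive", "inconclusive", "not active" in the trimmed comment, so
  "INACTIVE at 10uM" and "not active in counterscreen" are dropped along
  with bare flags. Comments are free text; the intent of the predicate is
  to remove inactivity reports, and containment errs on the side of data
  integrity for the high tier. (Note "inactive" contains no false
  positives from "active": containment of *inactive* never fires on the
  word "active" alone.)
- "Human" is the exact organism string `Homo sapiens`; taxonomy
  identifiers are out of scope.
- Filtering is per record, not per compound: a compound enters the high
  tier through its conforming records while its non-conforming records
  are dropped. Activity data are filtered first, compounds counted after.
- The comment and relation predicates apply only to the high tier; the
  low tier is deliberately permissive ("any reported interaction").

Both filters are idempotent, and the high output is a record subset of
the low output for every dataset; both properties are tested, and every
excluded record can be attributed to its failed predicates
(`explain_exclusions`).

## Time-course statistics

**Growth tables.** For one entity kind (compounds, targets, assays,
activities) the table lists per year the number of new entities and the
running cumulative count. A compound/target/assay is new in the earliest
year any of its records appears and is counted once; activity records
count in their own release year. Rows span the dataset's full year range
with explicit zeros for gap years. Fold increase between two years is the
ratio of cumulative counts, full precision internally, rounded to one
decimal only in reports.

**Promiscuity series.** Per compound, the cumulative distinct-target
degree for each year from its first record year to the horizon. A target
contributes from the earliest year it appears for that compound; later
re-measurements neither add nor reset anything, so the series is
non-decreasing. The horizon defaults to the latest release year in the
dataset.

**Annual mean.** The mean degree at year *y* is taken over all compounds
whose first year is ≤ *y* — every compound already seen remains in the
denominator whether or not new data arrived for it that year. This
cumulative denominator matches the per-compound framing above (a
compound's degree is defined every year after debut) and yields a smooth
series; years before the first debut are absent rather than zero.

**ΔPromiscuity.** The gain from the degree in the compound's *first* year
to the degree at the horizon. The baseline is the first-year degree, not
1: a compound that debuts with three targets and never gains another has
Δ = 0. Bins 0–5 singly, then 6–10, 11–20, 21–50, >50 — disjoint and
exhaustive over the non-negative integers, so the bin counts always sum
to the number of compounds.

**Cohorts.** The compounds whose earliest release year equals a given
debut year, with all their (also later) records. Cohorts over distinct
debut years partition the compound set. Cohort means are evaluated at the
same horizon as the global mean; default cohort debut years in the
pipeline are 1994 and 2004.

Degenerate inputs: an empty dataset yields an empty growth table and an
empty profile list (no error); the mean of an empty compound set is
undefined and raises; records without a release year must be split off
(`exclude_missing_release_year`) before any time-course operation, which
otherwise refuses them loudly.

## Synthetic data generator

The generator emulates the statistical shape of a public bioactivity
database accumulating records over 1976–2014:

- **Debut years** follow a configurable growth model. The default,
  `piecewise_exponential`, ramps the annual debut weight linearly
  (`1 + 0.25·(y − 1976)`) until the 2006 breakpoint, then jumps by ×3 and
  grows by ×1.15 per year — slow steady growth followed by steep growth,
  the qualitative pattern of the public corpus. A `linear` model is
  available for comparisons.
- **Final target counts** are drawn from a categorical distribution with
  default mass 0.985 on a single target and a thin tail over 2–55,
  reflecting how heavily real promiscuity distributions concentrate at
  one target.
- **Accretion**: a multi-target compound debuts with one target and
  gains the rest at uniform years strictly after its debut (the
  correctness of the pipeline must not depend on this choice; no
  empirical accretion model is claimed). With probability
  `debut_multiplicity` (default 0) it instead receives its full set in
  the debut year — a multi-target compound with Δ = 0, as real databases
  contain. Under the default, the configured single-target mass is
  exactly the expected Δ = 0 fraction, which is what the
  parameter-recovery test exploits.
- **Confidence attributes** are drawn per *target* (type, organism), per
  *assay* (relationship type, confidence score) and per *record*
  (measurement type, relation, comment, value missingness), so entity
  attributes are internally consistent. The default mix makes roughly 30%
  of records fully high-confidence-conforming — a default to exercise
  both tiers, not an assertion about any real corpus.
- **Repeats**: each compound–target pair receives 1–3 records (default
  80/15/5%), extra records at uniform later years; byte-identical
  collisions are deduplicated at emission.

All randomness flows from a single seeded NumPy generator stream, so a
seed fixes the dataset byte for byte. The emitted `GroundTruth` records
each compound's debut year, debut target count and final target set, plus
per-year new-entity tallies.

What the generator does *not* emulate: chemical structures, realistic
potency-value distributions, assay descriptions, correlation between a
compound's debut era and its eventual promiscuity beyond the shrinking
accretion window, or database-specific curation artifacts. Passing tests
therefore demonstrate that the pipeline computes its statistics correctly
on data with the stated longitudinal shape — not that any particular real
corpus has those statistics.

## Verification strategy

Every time-course statistic has an independent brute-force oracle
(`tests/_brute.py`) that rebuilds target sets from scratch by scanning
all records, per compound and per year, with no shared code; library and
oracle must agree exactly on hundreds of small random datasets. Published
reference tallies for a real corpus (1976/2014 cumulative counts,
promiscuity-gain bin counts) are used as *inputs* to the arithmetic
operations — cumulation, fold increase, bin conservation, constant-Δ
fraction — whose outputs are then checked to printed precision. Property
tests cover monotonicity of degrees, filter subset/idempotence, cohort
partitioning and write/read round-tripping. Statistical checks (parameter
recovery at n = 10,000 compounds; post-breakpoint growth exceeding the
pre-breakpoint linear extrapolation over several seeds) use fixed seeds
and 3-standard-error bands. Problem sizes in the suite — datasets of tens
to a few thousand compounds, one 10,000-compound recovery run — were
chosen to make each property decisive at desk scale.

## Known limitations

- Counts reflect database entries: no structure standardization, so
  salts/stereoisomers registered separately count separately.
- The final year of a real corpus is typically incomplete (records
  published late in the year arrive in later releases); that is a data
  property, not a code path — the horizon is simply the last year
  analysed.
- Promiscuity is targets-per-compound only; the transpose
  (compounds-per-target) is out of scope.
- No unit conversion or potency standardization across measurement
  types; values are carried through, not interpreted.
- No statistical hypothesis testing is performed; the outputs are
  descriptive tallies and means.
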