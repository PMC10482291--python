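# Methods

This note records the models, parameter choices and numerical conventions
behind `featherid`, and what the synthetic-data validation does and does
not demonstrate.

## Identification model

A field sample yields (ideally) one Sanger-style read per primer set.
Identification of a sample proceeds: quality trimming → HQ% computation →
local-alignment search of the reference database → tie resolution →
phenology check → tier classification, first on the primer-set-1 read and,
only if that ends in *no identification* (no amplicon, no hit at ≥ 95%
identity, or inconsistent phenology), on the set-2 read, keeping the
better outcome (positive > questionable > no identification; ties keep
set 1). The fallback fires only on failures — a questionable set-1
outcome is reported as such — because re-amplification is a recovery
step, not a second opinion.

The three tiers do not partition the criterion space on their own (a
sample can sit in different tiers on different criteria), so the
classifier is worst-tier-wins with a strict positive tier:

* no identification ⇔ identity < 95, or coverage < 30, or phenology
  inconsistent, or no reportable hit at all;
* positive ⇔ HQ% > 20 and coverage > 50 and identity > 97 and phenology
  consistent or unknown;
* questionable ⇔ everything else.

Boundary values (95, 97, 30, 50, 20) land in the questionable tier
because the positive-tier inequalities are strict. Phenology `unknown`
(species absent from the table) does not block a positive call:
phenology is treated as verification, not prerequisite. Reads without
quality scores (FASTA input) have HQ% "not assessable" and can never be
positive, which is the conservative reading of a missing quality signal.

Whether the general 95% criterion applies to identity alone or jointly
with coverage is genuinely open; it is implemented as identity-only, with
coverage handled by its own tiers.

## Alignment conventions

Alignment is exact Smith–Waterman with Gotoh affine gaps — no heuristic
seeding — which is affordable at this scale (hundreds of references ×
~600 bp reads) and makes rankings exactly reproducible. Conventions:

* scoring defaults: match +2, mismatch −3, gap open −5, gap extend −2; a
  gap of length k scores `open + (k−1)·extend`;
* identity counts gap columns as non-matches (BLAST-style); coverage is
  aligned query bases over query length;
* IUPAC codes match iff their expansion sets intersect, with no partial
  credit;
* traceback is deterministic: on score ties diagonal beats up beats left,
  openings beat extensions, and the start cell is the first maximum in
  row-major order;
* both query orientations are aligned and the better kept **by score**
  (score weighs length and identity together; selecting by identity
  would let a chance ~10 bp perfect match on the wrong strand displace a
  full-length 99% hit);
* ranking across references is identity desc, coverage desc, score desc,
  ref_id asc — identity first, as the primary match parameter;
* hits are reported down to 90% identity so that near-threshold (95%)
  cases remain visible;
* within 0.5 identity points of the best hit, the highest coverage wins;
  metric-identical distinct species are co-reported (the sister-taxon
  case, e.g. hybridizing teal or grebe pairs whose barcodes are
  identical).

An optional k-mer prefilter (k = 11, ≥ 1 shared k-mer, falling back to
the full database if nothing passes) exists for large databases and is
off by default.

## Phenology

Windows are (species, site-region) rows with day-of-year bounds that may
wrap the year boundary, each labelled `expected` or `marginal`. A date
inside an expected window is consistent; inside a marginal window, or
within `buffer_days` (default 14) of an expected boundary, unlikely;
otherwise inconsistent. The 14-day buffer quantifies the otherwise
qualitative "unlikely" tier and is configurable. Dates are mapped to a
fixed non-leap calendar (Feb 29 → day 60) so windows are comparable
across years; circular distances use a 366-day year.

## Quality statistics

HQ% is the percentage of bases with Phred quality at or above a
threshold, default Q20 (~1% error), the conventional Sanger high-quality
bar. The upstream provider-side definition of "high-quality resolution"
varies by vendor, so the Q20 definition is a documented, configurable
stand-in rather than a guess at any one vendor's metric. End trimming
slides a window (default 10 bases) from each end and cuts at the first /
last window whose mean quality reaches 20; a read with no acceptable
window trims to empty (the classifier then falls back to the raw read so
a uniformly mediocre read is still searched, just never positive-tier on
HQ).

## Deduplication

Two samples are candidate repeat finds of one individual when they share
species call, facility and calendar window, and their sequences are
identical — zero mismatches — over an aligned overlap of ≥ 400 bases
(the floor guards against trivially short reads; "identical sequences"
admits no mismatch tolerance). "Week" means ISO-8601 calendar week,
chosen over a sliding window for determinism; `sliding:<days>` is
available. Clusters are transitive closures (A≡B and B≡C merge even if
the two identities rest on different overlaps) and clustering is
invariant to input order. The reported duplicate fraction — cluster
members over total samples — is a *maximum*: flockmates can share a
mitochondrial haplotype, so the true fraction of repeat finds is lower.

## Community statistics

Orders map to Terrestrial Birds / Songbirds / Waterbirds through an
editable map (shipped default: Passeriformes → Songbird; Anseriformes,
Charadriiformes, Podicipediformes, Pelecaniformes → Waterbird;
Galliformes, Apodiformes, Accipitriformes, Falconiformes, Strigiformes,
Columbiformes, Caprimulgiformes, Piciformes, Cuculiformes → Terrestrial).
Unmapped orders are an explicit error — no silent bucket — so users with
an authoritative regional list can and should extend the map TSV.

The χ² test is Pearson's Σ(O−E)²/E with expectations from the marginals
and df = (r−1)(c−1). The p-value is computed in-package from the
regularized upper incomplete gamma function Q(df/2, x/2), by power series
for x < a+1 and by Lentz continued fraction otherwise (tolerance 1e-15,
max 2000 iterations); the test suite checks agreement with an independent
high-precision evaluation to 1e-8. No continuity correction by default
(intended tables are large-count; a Yates flag exists for 2×2), and no
multiple-testing adjustment (two planned comparisons). All-zero group
columns are dropped before testing rather than failing on a zero
marginal, and reports always print the n actually used. Row percentages
are rounded to the nearest integer for display; counts are exact.

Percentage summaries elsewhere (category tallies, rescue rates, blind
tests) round half-up via decimal arithmetic, one decimal by default.

## Synthetic data: what it emulates

The generator builds per-species mitochondrial-like templates: 5' flank,
the 512 bp set-1 amplicon (forward-primer cassette, filler,
reverse-complemented reverse cassette), the adjacent 596 bp set-2
amplicon, 3' flank. Cassettes are concrete expansions of the degenerate
primers and are held fixed; filler is i.i.d. uniform over ACGT (no codon
structure is needed for alignment-based identification). Species diverge
from a common ancestor by i.i.d. per-site substitutions at a rate solved
so the expected *pairwise* divergence equals the configured value (no
phylogeny is simulated — sufficient to exercise identity thresholds).
Sister pairs copy the amplicon region byte-for-byte (identity is confined
to the barcode locus, as in real sister species); accidental non-sister
collisions are redrawn with bounded retries. Amplicon lengths are
primer-inclusive: the published product sizes do not state whether they
include primers, so this artifact defines 512/596 as the full returned
product and the generator enforces that.

Surveys draw species by group composition (default Songbird 0.7 /
Waterbird 0.2 / Terrestrial 0.1), sites from eight facilities (five
photovoltaic, two parabolic trough, one power tower), and dates uniform
over a year. Degradation applies i.i.d. substitutions (default 1%),
end-truncation (20% of reads lose up to 20% from one end) and linearly
decaying qualities (Q40 minus 0.05/base, σ = 2 noise). PCR failure
(default 10%) reroutes a sample to the set-2 amplicon. Duplicate feather
spots (default 5%) re-emit an individual's read byte-identically at the
same site on the same or next day. Every read gets exactly one truth
ledger row, and all output is deterministic under the seed (one RNG
stream per operation, derived from the master seed by stable labels, so
results are independent of call order).

There is no field-calibrated degradation model for desert-exposed
feathers; these defaults are operating points chosen to be plausibly
harsh, not estimates. The generator also does not emulate chromatogram
artifacts, chimeric PCR products, contamination, or reference-database
gaps/errors. Passing the end-to-end tests therefore shows the *logic* is
correct under realistic noise magnitudes — it does not certify field
accuracy, which depends on reference completeness and real error modes.

## Problem sizes used in validation

The default synthetic study is 20 species / 300 samples; the acceptance
script runs exactly that. Unit and property suites use 8–12 species and
25–500 samples, 1000-pair alignment-oracle sweeps (≤ 200 bp) and
1000-table χ² sweeps. These sizes were chosen as the smallest that give
stable binomial checks (3-standard-error bands) at desk-scale runtimes.

## Known limitations

* Identity between equally optimal alignments is reported for the single
  deterministic traceback; a different but equally optimal alignment may
  have a different identity (symmetry is only guaranteed for full-overlap
  cases).
* Reads are searched against full-length reference templates; region
  labels (`amplicon1`/`amplicon2`) are informational and not used to
  restrict the search.
* The blind-test headline discrepancy rate counts ambiguous sister ties
  together with clean mismatches; the report also carries the split.
* No E-value model: with ~tens of references the identity/coverage floor
  makes spurious assignment unlikely, but against very large databases a
  significance model would be needed.
* AB1 chromatogram parsing and forward/reverse trace merging are out of
  scope; qualities must arrive via FASTQ.
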