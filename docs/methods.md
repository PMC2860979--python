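# Methods

## The problem

Three *Neocalanus* copepod species co-occur in the Northwestern Pacific —
*N. cristatus*, *N. plumchrus* and *N. flemingeri* — and *N. flemingeri*
additionally comes in a large and a small body-size form whose taxonomic
status is unresolved.  The question the pipeline addresses is operational:
given aligned sequences of several markers (mitochondrial COI and 12S,
nuclear ITS and 28S) for specimens labelled by species and form, can each
taxonomic level be told apart, and by which markers?  Two complementary
criteria are implemented:

* **distance-based** — pairwise divergence summaries and the *barcoding
  gap*: a group pair is separable when every between-group distance exceeds
  every within-group distance;
* **character-based** — individual alignment columns that diagnose a group,
  either *purely* (a base fixed in the group and absent everywhere else) or
  *privately* (a base exclusive to the group but not fixed in it), plus
  specimen assignment by voting over pure columns.

## Distances

The distance is the uncorrected proportion of differing sites, *p*.  No
substitution-model correction is applied in the empirical pipeline: at the
divergences involved (≤ 0.17) the correction is small, and *p* is the
conventional quantity in barcode-gap analyses.

Ambiguity handling is *pairwise deletion*: a column is dropped from one
pair's comparison when either sequence carries anything but a plain base
there (gap, or an IUPAC ambiguity code standing for an electropherogram
double peak).  The same column still counts for other pairs.  A pair with
no comparable columns has an *undefined* distance that propagates as
missing, never as zero.  Gaps are treated exactly like ambiguity codes
here; the alternative (complete deletion) is not offered because it would
discard whole columns for sporadic single-specimen artefacts.

Group summaries report mean and SD of *p* over the full between-group pair
set (|A|·|B| pairs) or within-group set (n(n−1)/2).  The SD defaults to the
sample estimator (n−1); a `population` switch exists for sensitivity
checks.  Note that *p* under pairwise deletion is not guaranteed to satisfy
the triangle inequality; no such property is assumed anywhere.

## Barcoding gap

For a group pair, within-distances of both groups are pooled and compared
with the between-distances: `gap_size = min(inter) − max(intra)`,
`has_gap = gap_size > 0`.  The verdict uses raw distances only — the
mismatch histograms (default bin width 0.005, half-open bins
[k·w, (k+1)·w)) are purely presentational, so `has_gap` is invariant to
binning.  Pooling the two groups' within-distances is a deliberate choice:
the alternative (per-group maxima) is recoverable from the per-category
histograms that are emitted alongside.

## Diagnostic characters

Columns pass two filters, in order:

1. **double-peak deletion** — any column where any specimen carries an
   IUPAC ambiguity code is removed outright (such codes are read as
   unresolved double peaks, possibly from nuclear copies of mitochondrial
   genes or incomplete concerted evolution of rDNA, so the column's states
   cannot be trusted for anyone);
2. **≥2-carrier rule** — a column is kept only if at least two specimens
   deviate from the modal base (gaps ignored).  A variant seen in a single
   specimen is indistinguishable from a sequencing error; requiring two
   carriers is the minimal error-suppression rule.  Under a modal tie the
   count of non-modal carriers still applies, which keeps exactly the
   columns where every tied state has at least the threshold of carriers.

Retained columns are classified per group by direct state-set comparison
(gaps contribute no state; a group that is all-gap at a column has an empty
set and status NONE):

* PURE: the group's state set is a singleton whose base occurs in no other
  group;
* PRIVATE: the set contains a base absent from every other group, but is
  not a singleton;
* NONE: otherwise.

The two statuses are mutually exclusive by construction.  Column
coordinates are 1-based alignment positions.

**Assignment** votes a query's character at every column PURE for some
group: a plain base votes for the group whose pure state it equals; a 2- or
3-fold ambiguity code votes for every group whose pure state it could
represent; gaps and `N` are information-free and never vote.  The group
with strictly most votes wins, ties or an empty tally yield UNASSIGNED.
PRIVATE states are reported but never vote — they are evidence of
distinctness, not identification characters, since absence of the private
base says nothing.

## Synthetic data generator

The generator exists so that every stage is testable end-to-end without
downloading the deposited sequences.  It emulates the study design:

* fixed rooted topology
  `(cristatus, (plumchrus, (flemingeri-large, flemingeri-small)))`;
* group sizes 8 / 8 / 16 / 5 (37 specimens);
* four loci with the study's divergence hierarchy, parameterised directly
  by the published between-group mean p-distances (COI: forms 0.03586,
  sibling species 0.154, species 0.162; 12S: 0.0045–0.086; ITS:
  0.0006–0.0066; 28S: 0.000–0.011) at lengths 658 / 500 / 900 / 400 bp;
* within-group diversity 0.006 (COI), 0.003 (12S), 0.001 (ITS), 0.000
  (28S) — matching the published within-group ranges (< 0.010 for COI,
  < 0.005 for 12S, < 0.002 for ITS, 0.000 for 28S);
* sporadic two-fold IUPAC codes (R/Y/S/W/K/M containing the true base) at
  rate 0.002 per base, emulating coded double peaks.  Only 2-fold codes are
  injected because a double peak is a 2-state event.

Divergence is expressed in Jukes–Cantor substitutions/site; JC69 is the
simplest model with a closed form `p_diff(d) = (3/4)(1 − e^(−4d/3))`
linking divergence to expected mismatch proportion, and that closed form is
the recovery oracle in the tests.  `evolve_jc` implements the plain
process: each site independently substitutes with probability `p_diff(d)`
to a uniformly chosen different base.

`simulate_dataset` itself realises branches under a **no-multiple-hit
conditioning**.  Branch budgets are solved additively on the
mismatch-proportion scale (tip-to-tip target p minus the two groups'
within-group depths, clipped at zero, then the usual four-taxon path
equations; the two forms' divergences to an outside group are averaged
since they share that path).  Each branch then substitutes
`stochastic-round(L·p)` columns drawn from a single shuffled per-locus pool,
so no column is ever hit twice and realised pairwise mismatch proportions
are exactly additive along paths.  Consequently every realised group
divergence equals its configured target to within ±1 site.  An
unconditioned realisation would carry the binomial noise of each shared
internal branch — SD √(p(1−p)/L) ≈ 0.014 for a COI-scale species pair —
which would swamp the narrow hierarchy the generator must reproduce across
seeds.  The price is that saturation and homoplasy are absent: every
variable column has exactly the history that produced it, within-group
variants never collide with diagnostic columns, and within-group distances
vary only through the stochastic rounding.  Passing tests therefore
demonstrate that the pipeline recovers the structure the generator encodes;
they do not exercise multiple hits, rate heterogeneity, indels (gap
handling is tested with hand-built fixtures instead), intragroup
coalescent structure, or numt/introgression artefacts beyond the ambiguity
coding itself.

Within groups the phylogeny is a star: each specimen is its group ancestor
evolved by half the within-group diversity.  That reproduces the
"within ≪ between" structure the analyses assume without modelling a
coalescent.

Clipping note: at 12S/ITS/28S the configured form-level divergence is at or
below the within-group diversity, so the solved ancestor separation clips
to zero and the expected between-form mean is the within-group level
(bias ≤ 0.0015) — which is precisely the regime in which no barcoding gap
and no pure characters should appear, and none do.

## Numerical and interface choices

* Sequences are stored uppercase; `U` is accepted on input and mapped to
  `T`.  Groups are opaque strings `species` or `species|form`; running the
  pipeline with `--grouping species` merges the forms without touching the
  data.
* Distance matrices are dense symmetric float arrays with NaN for
  undefined pairs; retained-column counts ride along in a parallel integer
  matrix.
* Histogram bins are half-open with the boundary in the upper bin.
* Assignment ties, empty tallies and undefined distances are all explicit
  outcomes, never exceptions.
* All randomness flows from a single `numpy` Generator seeded from the
  config, and pipeline outputs (TSV/JSON) are byte-deterministic for fixed
  inputs and parameters; the manifest records a SHA-256 per file.

## Problem sizes used in tests and the acceptance script

All end-to-end checks run on the study-scale simulation (37 specimens, four
loci, 658/500/900/400 bp — seconds per seed), plus 1,000 randomised small
alignments/pairs for the brute-force oracle comparisons.  These sizes were
chosen as the smallest that exercise the study design faithfully.

## Known limitations

* Alignments are taken as given; no alignment or chromatogram processing.
* No model-corrected distances in the empirical pipeline (JC appears only
  in the simulator's parameterisation).
* Diagnostic attributes are flat-group, single-column characters; no
  clade-hierarchical or compound attributes.
* Gap detection reports presence/size per declared grouping only; no
  automatic threshold-based delimitation.
* The published diagnostic-site labels (e.g. sites 068/121/268 of the COI
  amplicon) live in the original trimmed coordinate system; reproducing
  those exact labels requires recovering that trim from the deposited
  accession sequences, which the offline pipeline does not attempt.
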