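# neodiag

Distance- and character-based discrimination of species and intraspecific
forms from multi-locus DNA barcode alignments — built around the
*Neocalanus* copepod study design: three co-occurring species
(*N. cristatus*, *N. plumchrus*, *N. flemingeri*) plus the large/small
body-size forms of *N. flemingeri*, sequenced for mitochondrial COI and
12S and nuclear ITS and 28S.

For each marker alignment and a specimen table (`specimen_id`, `species`,
`form`), the pipeline computes:

1. **p-distances with pairwise deletion** — the uncorrected proportion of
   differing sites per pair, excluding columns where either sequence has a
   gap or an IUPAC ambiguity code (coded electropherogram double peaks);
   group-pair mean (SD) tables in the conventional multi-marker layout.
2. **Mismatch distributions & barcoding gaps** — histograms of pairwise *p*
   by comparison category, and for each group pair the gap verdict
   `min(inter) − max(intra) > 0` computed from raw distances.
3. **Diagnostic characters** — after deleting double-peak columns and
   columns whose variation occurs in fewer than two individuals, each
   retained column is classified per group as **PURE** (one base fixed in
   the group, absent elsewhere), **PRIVATE** (a base exclusive to the group
   but not fixed in it) or NONE.
4. **Specimen assignment** — a query sequence votes at every PURE column
   and is assigned to the group with strictly most matches.
5. **Synthetic data** — a seeded Jukes–Cantor generator reproducing the
   study design (four groups on the fixed topology
   `(cristatus,(plumchrus,(large,small)))`, 8/8/16/5 specimens, four loci
   with the published divergence hierarchy, sporadic two-fold ambiguity
   codes), so the whole pipeline is testable offline.

## Worked example

Simulate the study-scale dataset and run every stage:

```bash
neodiag simulate --seed 0 -o results/simulated
neodiag all results/simulated/*.fasta \
    -m results/simulated/specimens.tsv -o results/full
```

Or run the numbered drivers under `analysis/` (same computation, narrated):

```text
$ python analysis/02_distances.py
comparison                                  12S                28S                COI                ITS
N. cristatus VS N. plumchrus                0.07752 (0.00112)  0.01004 (0.00002)  0.16242 (0.00089)  0.00656 (0.00079)
...
N. flemingeri|small VS N. flemingeri|large  0.00459 (0.00136)  0.00000 (0.00000)  0.03638 (0.00051)  0.00157 (0.00070)
within N. flemingeri|small                  0.00274 (0.00127)  0.00000 (0.00000)  0.00591 (0.00051)  0.00181 (0.00060)

$ python analysis/03_mismatch_gap.py
form-level (flemingeri large vs small) barcoding gap by marker:
  12S  max intra 0.0040  min inter 0.0020  -> no gap
  28S  max intra 0.0000  min inter 0.0000  -> no gap
  COI  max intra 0.0062  min inter 0.0350  -> GAP
  ITS  max intra 0.0022  min inter 0.0000  -> no gap

$ python analysis/05_assign_forms.py
...
21/21 flemingeri specimens assigned to their true form
```

Reading the numbers: between-group mean *p* at COI is ~0.16 between
species and ~0.036 between the two *N. flemingeri* forms, while every
within-group mean stays below 0.01 — so COI separates even the forms by a
clean distance gap (max intra 0.006 < min inter 0.035).  The nuclear
markers put the forms at or below their own within-group diversity: no
gap, no pure characters, no identification.  The forms are nonetheless
perfectly assignable from COI alone: ~19 reciprocally fixed (PURE) columns
give every specimen an unambiguous vote.  That marker-dependence — species
separable everywhere, forms separable only mitochondrially — is the
analysis's central result.

To analyse real data instead, point the same commands at your own aligned
FASTA files and metadata TSV.  `scripts/fetch_accessions.py` (network
required) downloads the deposited study sequences AB526881–AB527004 from
GenBank, bucketed per marker, for realignment with e.g. `mafft`.

## Layout

```
src/neodiag/        library: alignment_io, distance, gap_analysis,
                    diagnostics, synthetic_data, report, cli
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite (unit, property and end-to-end checks)
scripts/            acceptance.py, fetch_accessions.py
docs/methods.md     models, parameters, design choices, limitations
```
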