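# Methods

## Problem and model

Grafting two plant species creates a chimeric organism in which RNAs can
cross the graft union. Because the two genomes are distant, a small RNA
sequenced from one member's tissue but encoded only by the other member's
genome is direct evidence of transport. `graftmir` implements this logic as
a deterministic, testable pipeline:

1. **Cleaning.** Raw reads are trimmed at the leftmost occurrence of the
   first `min(8, len)` bases of the 3' adaptor; inserts outside 18–30 nt or
   with more than three `N` bases are rejected, each rejection attributed to
   one reason so that per-sample totals are conserved exactly.
2. **Collapsing.** Clean inserts collapse to unique tags with one read
   count per sample. The tag sequence — not a locus or an isomiR cluster —
   is the unit of all downstream inference.
3. **Annotation filtering.** A tag is removed when its sequence or reverse
   complement occurs verbatim inside any annotation sequence (rRNA / tRNA /
   snRNA / snoRNA / repeat stand-ins). Survivors are the "total sRNA" set.
4. **Hierarchical assignment.** Tags are matched full-length against the
   tissue's own genome first; only tags with *no* own-genome hit are
   re-mapped against the partner genome. Matching is exact by default
   (`max_mismatches = 0`), seeded by a k-mer hash index (k = 12) over the
   forward strand; minus-strand hits are found via the reverse complement
   of the query. With `max_mismatches = 1`, seeding additionally enumerates
   every 1-substitution variant of the first k-mer, which is complete for a
   single substitution at any tag length ≥ k (a second exact seed at offset
   k alone would miss substitutions falling in the overlap of the two seed
   windows when tags are shorter than 2k).
5. **Mobility calling.** A partner-assigned tag is **called** iff every
   self-graft control replicate has zero reads and the heterograft
   replicates together carry at least `min_hetero_reads` (default 1) reads.
   Presence in every heterograft replicate is *not* required — the
   operative rule is control absence; a stricter all-replicates rule is
   available via `min_hetero_replicates`. Candidates identical (sense
   strand) to an entry of the tissue species' own catalog are demoted to
   `ambiguous_shared`: their origin cannot be decided. Antisense identity
   is recorded as a strand note, not an exclusion, since a star strand
   travelling in the opposite polarity is a distinct molecule.
6. **Family annotation.** The nearest equal-length catalog entry within 3
   substitutions (sense or antisense) names the family; ties break
   lexicographically by entry name (logged). Calling, shared-flagging and
   family annotation are direction-symmetric: the shoot-to-root direction
   is the same code with tissue roles swapped in the manifest.
7. **Precursor vetting.** Each exact genomic hit of a called mature is
   expanded by ±150 nt, oriented to the hit strand, and scored by the
   maximum number of nested base pairs (Watson–Crick plus G·U wobble,
   minimum loop 3) via the standard base-pair-maximization dynamic
   program. Windows are ranked by pairs per nucleotide with no hard
   verdict, since no principled universal cutoff exists for plant
   pre-miRNAs. Transcript classification: `mature` at exact mature length;
   `pre` at ≤ 300 nt with ≥ 0.25 pairs/nt; `pri` otherwise (sequences over
   300 nt are classified `pri` without running the cubic DP).
8. **qPCR quantification.** ΔCt = Ct(assay) − Ct(U6) per biological
   replicate after averaging technical replicates; summaries are mean ± sd
   over biological replicates (the assay design is 3 biological × 2
   technical). ΔCt is invariant to plate-wide Ct shifts; 2^(−ΔCt) restores
   a monotone abundance scale. Expression binning uses
   log10(RPM + ε) against edges (−1, 0.5, 1.5, 2.5) for five classes from
   `extremely_low` to `ultra_high`, with ε the RPM of half a read; a count
   of zero is always `extremely_low`. The class boundaries are
   configuration values, not biologically derived constants.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_len` / `max_len` | 18 / 30 nt | clean-insert length window |
| `max_unknown_bases` | 3 | maximum `N` per insert |
| `adaptor_3p` | `TGGAATTCTCGGGTGCCAAGG` | small-RNA 3' adaptor |
| `k` | 12 | index k-mer size (≤ `min_len`) |
| `max_mismatches` | 0 | substitutions tolerated in genome matching |
| `min_hetero_reads` | 1 | total heterograft reads needed to call |
| `min_hetero_replicates` | 1 | heterograft replicates with ≥ 1 read |
| `precursor_flank` | 150 nt | window flank around a mature hit |
| `pre_max` / `min_pairs_per_nt` | 300 nt / 0.25 | pre-miRNA length/pairing bar |
| `expression_bins` | (−1, 0.5, 1.5, 2.5) | log10 RPM class edges |

Exact matching is the deliberate default: mobility calls are sequence-level
claims, and a single tolerated substitution would let a variant tag be
absorbed by a near-identical locus of the recipient genome. Both settings
are supported and the assigner is oracle-tested at 0 and 1 mismatches.

## The synthetic generator

`SimDesign` defaults encode the emulated study: two species (`At` scion
species, `Nb` rootstock species), 3 heterograft + 3 self-graft replicates
per tissue, 14 loci per species (8 unique, 4 variant, 2 shared), 50 000
reads per library, 8 shoot-to-root and 6 root-to-shoot mobile loci,
mobile fraction 0.2, per-base error rate 0.001, 95 % adaptor read-through,
20 % background reads split between annotation decoys and random own-genome
fragments.

Design choices worth knowing:

* **Abundance.** Per-locus abundance is log-uniform on [1, 10⁴]
  (populating all five expression classes) and is normalized so a sample's
  expected miRNA yield is `depth × (1 − background_fraction)`.
* **Delivery guarantee.** A mobile locus contributes
  `mobile_fraction ×` its donor-side expected reads to each heterograft
  replicate, stochastically rounded with a floor of one read whenever
  `mobile_fraction > 0`. The generator thus models the regime where mobile
  candidates are repeatedly detectable across heterograft replicates;
  sub-single-read mobility is outside its scope. This is what makes exact
  truth recovery a meaningful acceptance property rather than a coin flip.
* **Reproducible streams.** Every random decision draws from a stream
  keyed by SHA-256 of `(seed, stage, sample, locus)`. The per-(sample,
  locus) count uniform is drawn first and error masks are laid out
  row-major, so increasing `mobile_fraction` at a fixed seed can never
  decrease a locus's perfect-read count (the monotonicity invariant holds
  exactly, not just in expectation).
* **Genome disjointness.** Variant matures differ by one *central*
  substitution, so no ≥ 18-base run is shared; after assembly the two
  genomes are verified to share no 18-mer in either orientation outside
  shared-locus regions (padded by k − 1, since a window overhanging a
  shared region by one base can coincide by chance).
* **Adaptor read-through** below 1.0 applies to background reads only;
  miRNA-derived reads always carry the adaptor. Otherwise the single
  guaranteed read of a low-abundance mobile locus could be lost to the
  `no_adaptor` filter and truth recovery would be noise-limited.

What the generator does **not** emulate: quality-score structure (all
bases get one fixed quality), indels, ligation bias, isomiR heterogeneity,
expression differences between tissues, and genome repeat structure.
Passing truth-recovery tests therefore demonstrate the correctness of the
pipeline's logic under its stated assumptions — not its robustness to real
library artifacts.

## Numerical choices

* Percentages are rounded half-away-from-zero to two decimals
  (`Decimal`-based, matching printed accounting tables); a zero
  denominator renders `NA`.
* Coordinates are 0-based half-open internally, 1-based inclusive in every
  report.
* Report tables are written with documented sort keys and a stable sort,
  so re-running produces byte-identical files.
* The internal alphabet is DNA (`U → T` on read); catalogs and candidate
  sequences are rendered back as RNA in reports.
* Family tie-breaks are lexicographic by catalog entry name, sense before
  antisense, and are logged.

## Problem sizes used by the test suite

Oracle-equivalence checks use ≤ 10 kb genomes with 1 000 random tags at 0
and 1 mismatches against an exhaustive sliding-window scan; truth-recovery
runs five seeds of the full 12-library design at 50 000 reads per library;
the hairpin DP is checked against exhaustive structure enumeration for
sequences up to 18 nt. These sizes exercise every code path while keeping
the whole suite in the one-minute range on a single CPU.

## Known limitations

* Mobility evidence is presence/absence; no differential-abundance
  statistic is computed, matching the stringent rule implemented.
* Shared sequences are undecidable by design; the pipeline reports them
  (`ambiguous_shared`) rather than guessing.
* The hairpin score is a pairing count, not a thermodynamic free energy;
  it ranks windows but does not validate Drosha/Dicer processing.
* With `max_mismatches = 1`, a variant tag one substitution away from a
  recipient-genome locus is absorbed as "own" and cannot be called — the
  conservative failure mode.
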