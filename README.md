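# graftmir

Identification of graft-transmissible (mobile) miRNAs from cross-species
small-RNA sequencing.

When two distantly related plants — e.g. an *Arabidopsis thaliana* scion on
a *Nicotiana benthamiana* rootstock — are grafted, small RNAs can cross the
graft union. Because the genomes are distant, a sequenced small RNA that
maps to the *partner's* genome but not to the genome of the tissue it was
extracted from is direct evidence of long-distance transport. `graftmir`
turns this idea into a reproducible pipeline for researchers analysing
heterograft small-RNA libraries:

* read cleaning (3' adaptor, 18–30 nt, ≤ 3 `N`) and collapsing to unique
  tags with per-sample counts;
* annotation filtering (rRNA/tRNA/snRNA/snoRNA/repeat) by exact substring
  match on both strands;
* hierarchical two-genome assignment: a tag is matched full-length against
  the tissue's own genome first and only own-unmapped tags are re-mapped
  to the partner genome (exact matching by default, optional 1 mismatch),
  with full per-sample read accounting;
* the stringent mobility call: a partner-derived tag is **called** iff it
  has zero reads in every self-graft control replicate and ≥ 1 read across
  the heterograft replicates, with family annotation, antisense strand
  notes, and exclusion of sequences shared verbatim between the two
  species' catalogs (their origin is undecidable);
* precursor vetting by hairpin base-pair maximization around each genomic
  hit, and pri/pre/mature transcript classification;
* stem-loop RT-qPCR ΔCt quantification against the U6 reference and
  RPM-based expression-class binning;
* a synthetic heterograft generator (two toy genomes with planted shared /
  variant / unique miRNA loci, a controllable mobile fraction, sequencing
  error and adaptor read-through) so the whole pipeline runs at desk scale
  with known truth.

The core call rule, for tag *t* with heterograft replicate counts
*h₁…h_n* and self-graft control counts *c₁…c_m*:

    called(t)  ⇔  t maps to the partner genome only,
                  Σᵢ hᵢ ≥ min_hetero_reads,  and  cⱼ = 0 ∀ j

Larger ΔCt = Ct(miRNA) − Ct(U6) means lower abundance; 2^(−ΔCt) is the
relative quantity.

## Worked example

Simulate a small heterograft experiment (12 libraries: AGS/ACS scions,
NGR/NCR rootstocks, 3 replicates each) and run the full pipeline:

```sh
cat > design.yaml <<EOF
seed: 7
library_depth: 5000
error_rate: 0.0
EOF
graftmir simulate --design design.yaml --out-dir sim
graftmir run-all --manifest sim/manifest.tsv \
    --genome At=sim/genome_At.fa --genome Nb=sim/genome_Nb.fa \
    --annotations sim/annotations.fa \
    --mirna-catalog At=sim/catalog_At.fa --mirna-catalog Nb=sim/catalog_Nb.fa \
    --out-dir out
```

which prints

```
simulated 12 libraries under sim
rootstock: 8 called candidates (8 families)
scion: 6 called candidates (6 families)
```

— the 6 root-to-shoot and 8 shoot-to-root mobile loci planted by the
default design, recovered with no false positives (compare
`out/candidates_scion.tsv` against `sim/truth.tsv`). The candidate table
has the familiar layout — mature sequence (RNA), length, family, one count
column per replicate, plus status and strand note:

```
sequence               length  family   strand_note  AGS1  AGS2  AGS3  ACS1 ...
CCACUGGGACAAUCAAGACCA  21      miR1446  sense        8     8     8     0
CCCUAGAGUUCAGCAUGAUUC  21      miR162   sense        82    82    81    0
UAAACCUUGUCCAUUUUGAAA  21      miR166   sense        1     1     1     0
```

and `out/accounting_scion.tsv` carries the per-sample read accounting
(total → clean → annotation-removed → total sRNA → mapped own % →
re-mapped to partner %), e.g.

```
sample_id  total_reads  clean_reads  clean_pct  annotation_removed  total_srna  mapped_own  mapped_own_pct ...
ACS1       5000         4945        98.9       479                 4466        4466        100.0
```

Self-graft controls re-map 0 reads to the partner genome, as they must.
The individual stages are also available as `graftmir clean`, `assign`,
`call`, `precursor` and `quant` (see `graftmir <cmd> --help`).

## Layout

```
src/graftmir/
  io.py         readers/writers, manifest, configuration
  readqc.py     cleaning, collapsing, percentage accounting
  assign.py     k-mer index, matching, annotation filter, assignment
  caller.py     mobility calling, families, shared-sequence exclusion
  precursor.py  hairpin DP, precursor windows, pri/pre/mature classes
  qpcr.py       ΔCt quantification, expression binning
  simulate.py   synthetic heterograft generator with truth table
  pipeline.py   per-direction orchestration
  cli.py        graftmir command-line interface
docs/methods.md   model, assumptions, parameter rationale, limitations
```
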