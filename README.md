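# regcode

Integrative identification and classification of plant distal regulatory
regions from epigenomic and transcriptomic tracks.

## The problem

In plants, active regulatory regions — promoters and enhancers alike —
carry H3K27ac, while H3K4me1 marks gene bodies rather than enhancers.
A distal H3K27ac peak (≥ 2 kb from the nearest annotated gene) may
therefore be a genuine enhancer, or a misannotated gene betrayed by a
nearby H3K4me1 peak. Enhancers themselves differ in whether they produce
non-coding enhancer RNAs (eRNAs) from both DNA strands, one strand, or
neither; bidirectionally transcribed enhancers resemble animal
"super-enhancers" — more accessible, more TF-bound, intrinsically
stronger in reporter assays, and flanked by 24nt-siRNA/RdDM signal at
their borders.

`regcode` implements this integration for anyone working with maize-like
genomes: it classifies distal H3K27ac peaks into six classes

```
{H3K4me1 within 1 kb, no H3K4me1} × {bidirectional, unidirectional, no RNA}
```

and layers orthogonal evidence onto each peak: transcription-factor
binding sites, 5′-capped transcription (RAMPAGE-style), reporter
activity (STARR-seq-style), Hi-C chromatin-loop linkage to genes, and
conserved non-coding elements. Around the core classification it
provides the supporting machinery such a study needs:

- pseudo-replicate peak reproducibility filtering, local/distal
  partitioning, feature annotation and upset-style intersection tables;
- mappability masking by exact k-mer uniqueness of 150 bp genome bins,
  and size-preserving random control regions shuffled within the
  mappable space;
- reference-point and scaled-region signal metaprofiles, with a
  boundary-enrichment statistic for border-focused signals (24nt
  siRNAs, mCHH islands);
- tissue-specific differential-expression set logic (differential in one
  tissue versus *every* other tissue), expression quintiles, and a
  cross-inbred homolog-conservation flow;
- small-RNA size distributions (CPM), cluster strand-bias and
  hairpin-locus flagging, and telomere-repeat counting at chromosome
  ends;
- a synthetic-data generator that plants known truth for every one of
  these stages, so the full pipeline is testable without any download.

A strand is called "expressed" within a peak when its estimated read
count — coverage area over the peak divided by the read length — reaches
a threshold (default 5 reads); class membership follows from the two
strand calls and H3K4me1 edge-distance ≤ 1 kb. Activity differences
between classes are tested with two-sided Welch t-tests.

## Worked example

```python
from regcode import (SyntheticConfig, generate_dataset, classify_enhancers,
                     partition_local_distal, activity_compare)

bundle = generate_dataset(SyntheticConfig(seed=1))      # 600 distal peaks, 100/class
local, distal = partition_local_distal(bundle.k27ac, bundle.genes)
records = classify_enhancers(distal, bundle.k4me1, bundle.rna)

from collections import Counter
print(Counter(r.class_label for r in records))
# Counter({'K4me1+:unidirectional': 100, 'K4me1-:bidirectional': 100,
#          'K4me1+:bidirectional': 100, 'K4me1-:none': 100,
#          'K4me1-:unidirectional': 100, 'K4me1+:none': 100})

cmp_ = activity_compare(records, bundle.activity, summary="median")
print({k: round(float(v.mean()), 2) for k, v in cmp_.values.items()})
# {'K4me1+:unidirectional': 1.98, 'K4me1-:bidirectional': 3.06,
#  'K4me1+:bidirectional': 2.97, 'K4me1-:none': 1.05,
#  'K4me1-:unidirectional': 1.99, 'K4me1+:none': 1.01}
```

Each distal peak lands in exactly one class, the planted 100-per-class
structure is recovered in full, and the median reporter activity orders
bidirectional > unidirectional > silent enhancers, the signature of
bidirectionally transcribed "super-enhancers".

The same operations are exposed on the shell via the `regcode` command
(`regcode simulate`, `regcode classify`, `regcode mask`,
`regcode shuffle`, `regcode telomeres`, …); every command consumes and
produces plain text (BED/GFF3/BEDPE/bedGraph/FASTA/TSV).

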