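# svhotspot

Structural-variant simulation, discordant mate-pair calling and
junction-sequence analysis for a rearrangement hotspot locus — built around
the recurrent rearrangements of *TP53* intron 1 in osteosarcoma and
Li-Fraumeni syndrome.

The package is aimed at method developers and genomicists who want a fully
synthetic, truth-aware reconstruction of that analysis: every stage runs on
simulated data with exact ground truth, so recovery can be measured instead
of assumed.

## What it does

* **`genome_forge`** — random references; planted deletions, inversions,
  reciprocal translocations and inverted insertions with explicit junction
  mechanics (micro-homology, junctional duplication, untemplated insertion,
  net loss); mate-pair (DNA-PET-style) library simulation from 1–4 kb
  fragments with 2×35/2×50 bp tags; noisy log2-ratio and B-allele-fraction
  tracks. Everything is seeded and emits BEDPE/SAM/FASTA/FASTQ/TSV truth.
* **`dpet_caller`** — insert-size model (median/MAD), concordance
  classification, single-linkage clustering of discordant pairs (a cluster's
  size is its supporting-pair count), per-side breakpoint intervals, typed SV
  calls (DEL/INV/TRA/INS, balanced where reciprocal clusters pair up), and
  tumor/normal somatic subtraction.
* **`capture_filter`** — targeted-capture breakpoint discovery: keep pairs
  with exactly one end in the target, cluster the mates, rank by cluster
  size.
* **`junction_lens`** — exact junction-sequence analysis: micro-homology vs
  untemplated insertion at single junctions; for balanced derivative pairs,
  the signed length of locus sequence present on **both** derivatives
  (positive = junctional duplication, negative = net loss); spacing/overlap
  of two events at one locus.
* **`cn_transitions`** — penalized binary-segmentation of probe tracks,
  classification of copy-number transitions inside a gene window
  (into-loss / into-gain / loss-to-gain), and copy-neutral LOH detection
  from BAF tracks.
* **`hotspot_report`** — breakpoint recurrence across samples, an in-silico
  break-apart FISH scorer (≥ 10 % positive-cell rule), cohort percentage
  pooling, and the 2^−ΔΔCq fold-change utility.

The junction model follows the overhang fill-in mechanism: a double-strand
break with long single-stranded overhangs is filled in on both products, so
balanced events can carry the *same* 46–555 bp reference segment on both
derivatives — the signature this package measures exactly.

## Worked example

Plant the 94 kb gene-spanning deletion in a 2 Mb synthetic chromosome,
simulate a diploid 15× mate-pair library, round-trip through SAM, and call:

```python
from svhotspot import showcase

out = showcase.ajf_deletion_call(seed=11)
print("DEL span:", out)

sig = showcase.yzh_shared_segments(seed=4)
print("YZH:", sig)
```

prints

```
DEL span: {'span_kb': 94, 'span_bp': 94209, 'n_pairs': 19529}
YZH: {'shared_tp53_bp': 555, 'shared_chr1_bp': 293, 'class': 'duplication'}
```

The deletion call's span (94,209 bp from ~19.5k simulated pairs, i.e. 94 kb
to the nearest kb) is measured from the apparent-insert excess of the
supporting cluster, not read from the truth record. The second call
reconstructs the balanced translocation whose derivatives both retain 555 bp
of the gene locus and 293 bp of the partner locus; `analyze_balanced_pair`
recovers both lengths exactly and classes the mechanism as junctional
duplication.

The same stages are scriptable from a shell:

```bash
svhotspot forge --config forge.json --out-dir sim --seed 5
svhotspot call --sam sim/pairs.sam --out calls.bedpe
svhotspot report --calls-dir calls/ --window intron1.bed --out report.json
```

## Documentation

The model, its assumptions, parameter defaults and known limitations are
described in `docs/methods.md`.
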