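# tantseq

Chemistry-aware analysis of small-RNA 3′ ends.

Small RNAs of 15–30 nt terminate in one of three chemistries: a 3′-hydroxyl
(3′-OH), a 3′-monophosphate (3′-P) or a 2′,3′-cyclic phosphate (3′-cP).
Conventional small-RNA-seq ligates only 3′-OH ends and is blind to the cP
pool, which includes abundant ribonuclease cleavage products such as
tRNA-derived fragments. A dual-chemistry library scheme solves this at the
bench: T4 Rnl2 ligates a barcoded adapter to 3′-OH species (barcode
`GACGTA`), alkaline phosphatase plus periodate oxidation destroys the
ligatable ends of 3′-P species, and RtcB ligates a second barcoded adapter
to 3′-cP species (barcode `CTATCG`), so one sequencing run carries two
sublibraries distinguished by a terminal 6-mer.

`tantseq` implements everything downstream of the sequencer, plus the
companion assays:

- **simulate** — a chemistry-faithful read generator (toy reference tiers,
  ground-truth species with a pyrimidine|purine bias at cP 3′ ends, the
  9-member spike-in panel at 8/0.8/0.08 nM, ligation-efficiency effects,
  periodate dropout of 3′-P species) used as the test bed for every stage.
- **preprocess** — 3′-adapter trimming that keeps the barcode, mean-Phred ≥ 30
  and 21–46 nt filtering, and exact-match demultiplexing into the 3′-OH and
  3′-cP sublibraries.
- **classify** — two-round sequential mapping against priority-ordered
  reference tiers (spike-ins, rRNA, tRNA (+CCA), mt-tRNA, miRNA, piRNA,
  snRNA, snoRNA, lncRNA, miscRNA, intron, mRNA, repeat, genome): round 1
  exact, round 2 allowing mismatches + gaps ≤ 2; biotype labels
  (srRNA, tsRNA, sinRNA, slncRNA, sgmRNA, smRNA, srpRNA, smcRNA, …),
  tsRNA subtypes (5′-, 3′-CCA-, 3′-CC-, internal), and the dual
  nomenclature, e.g. full name `snRNA|s1|1|16|cP` and simple name
  `snR-2-cP` (biotype prefix, abundance rank, 3′ chemistry).
- **quantify** — ligation-efficiency-adjusted OH/cP percentages, length and
  precursor-coordinate distributions, terminal 5-nt composition/enrichment
  matrices, replicate Pearson correlation (log2(count+1)), top-N overlap.
- **diffexp** — CPM normalisation, a conditional exact binomial test per
  species, Benjamini–Yekutieli adjustment, and calls at adjusted
  P < 0.01 and |log2FC| ≥ 2.
- **teqpcr** — the triplex 3′-end qPCR estimator. With Ct values from
  vehicle, alkaline-phosphatase and T4 Pnk treatments,

  cP% = (2^ΔCt − 1)/2^ΔCt with ΔCt = Ct[3′-(OH+P)] − Ct[3′-(OH+P+cP)],
  P% = (2^ΔCt′ − 1)/2^ΔCt′ − cP% with ΔCt′ = Ct(3′-OH) − Ct[3′-(OH+P+cP)],
  OH% = 100% − P% − cP%.

- **cleave** — guide–target duplex alignment and Ago2 slicer-site
  prediction: the target is cut between the nucleotides paired with guide
  positions 10 and 11, with 5′/3′ product sequences derived; fraction
  cleaved = d₅ / (d₅ + d_uncleaved).

## Worked example

```python
>>> from tantseq.teqpcr import CtTriple, estimate_end_fractions
>>> estimate_end_fractions(CtTriple(22, 21, 20)).as_tuple()
(25.0, 25.0, 50.0)
```

One cycle of ΔCt between the AP and T4 Pnk treatments means half the
template carries a cyclic phosphate; two cycles between vehicle and T4 Pnk
leave 25% 3′-OH, so the remaining 25% is 3′-P.

```python
>>> from tantseq.classify import reverse_complement
>>> from tantseq.cleavage import align_duplex, predict_cleavage_site, product_sequences
>>> target = "GATTACAGATTACAGATTACAGATTACAGATT"
>>> guide = reverse_complement(target[4:26])          # 22-nt guide
>>> duplex = align_duplex(guide, target)
>>> predict_cleavage_site(duplex)
(10, 11, 16)
```

The scissile bond sits between the target bases paired to guide nucleotides
10 and 11 — here after target position 16, so the 5′ product is 16 nt.

A full simulated run (reads → sublibraries → species table → DE calls):

```bash
tantseq run-all --out-dir run1 --seed 5 --n-species 150 --depth 20000
```

writes `species_table.tsv` (per-species counts, biotypes, names),
`de_results.tsv`, length/terminal-composition tables, and `manifest.json`
with telescoping per-stage read counts.

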