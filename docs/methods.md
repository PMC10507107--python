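# Methods

## The library chemistry the software models

A small RNA's 3′ end records how it was made: RNA polymerase products and
exonucleolytic trimming leave 3′-OH; many endoribonucleases (RNase A
family, including angiogenin and RNase 4) cut 3′ of pyrimidines through a
2′,3′-cyclic intermediate, leaving 3′-cP; kinases and some nucleases leave
3′-P. The dual-chemistry prep captures the OH and cP pools in one run:

1. T4 Rnl2 ligates an adapter carrying barcode `GACGTA` to 3′-OH species.
2. Alkaline phosphatase converts 3′-P to 3′-OH, then periodate oxidises all
   free 3′-OH (cis-diol) ends to dialdehydes — so the original 3′-P pool is
   chemically removed from the library.
3. RtcB ligates an adapter carrying barcode `CTATCG` to the surviving
   2′,3′-cP species.

Every read is therefore `insert + 6-nt barcode + constant 3′ adapter`, and
the barcode is a ground-truth chemistry label. The two default barcodes
differ at all six positions, so exact matching cannot cross-assign a read
with fewer than six sequencing errors in the barcode.

## Preprocessing

Trimming removes the longest read suffix that matches a prefix of the
adapter with at least 8 nt overlap and at most one mismatch, keeping the
barcode. The quality filter keeps reads whose **mean** Phred is ≥ 30 —
the upstream trimmer this emulates actually uses a qualified-base
percentage rule, and that alternative (`quality_rule="fraction"`, ≤ 20% of
bases below threshold) is available; the mean rule is the default because
it is unambiguous and the simulator's quality model (uniform per-read
quality) makes the two rules coincide. The 21–46 nt window applies to the
barcode-attached read, i.e. 15–40 nt inserts. Demultiplexing is exact
(0 mismatches): sensitivity is deliberately traded for the
zero-cross-contamination guarantee the downstream chemistry comparisons
rest on.

## Tiered two-round classification

References are organised as priority-ordered tiers; tRNA tiers get `CCA`
appended once, unconditionally, at load (genomic tRNA references are
CCA-less; a per-tier flag disables this for users supplying mature
sequences — appending is *not* idempotent by design, the loader never
second-guesses its input). Round 1 walks tiers in priority order accepting
only exact placements; round 2 re-walks them accepting edit distance ≤ 2,
where substitutions and each gapped position cost 1. The first tier with a
hit wins, so an exact hit to a late tier beats a 1-edit hit to an early
tier, matching the two-pass design.

The search is a bounded semi-global scan: the full query must lie inside a
reference window, minimising cost over windows. Candidate windows come
from an edit-distance pigeonhole (split the query into k+1 parts; any
placement within k edits contains one part exactly), then a small
Levenshtein DP scores each candidate. `N` matches nothing, including `N`.
Ties break deterministically: fewer edits, lexicographically smaller
reference id, leftmost start, `+` strand before `−`, smallest end.
Transcript tiers are searched sense-strand only (small RNAs are sense
fragments of their precursors); genome and repeat tiers are searched on
both strands. Coordinates are 1-based inclusive on the (CCA-appended)
reference. An override table (sequence or reference id → biotype) mirrors
manual curation of known misassignments and logs every change.

tsRNA subtypes on the CCA-appended precursor: start 1 → 5′-tsRNA; end at
the precursor end with suffix `CCA` → 3′-CCA-tsRNA; end one short with
suffix `CC` → 3′-CC-tsRNA; otherwise internal. A full-length fragment
satisfies both the 5′ and 3′ conditions and is called 5′ (documented
precedence).

Naming: the full name is `{biotype}|{reference}|{start}|{length}|{mod}`
(the pipe-delimited layout is this package's convention; only its
ingredients are canonical). The simple name `{prefix}-{rank}-{mod}` ranks
species by mean raw reads within each (biotype, chemistry) group,
descending, ties by lexicographic sequence, and is assigned only when mean
reads strictly exceed 2. Rank is per dataset (on the mean across samples),
and "mean reads" means raw, unnormalised counts.

## Quantification

Raw OH and cP totals are divided by their ligation efficiencies before
forming percentages (`adjusted = raw/eff`). Efficiencies default to 1.0
and must be user-measured for real libraries — they are instrument/enzyme
properties, not estimable from a single library. Terminal composition is
tallied over the outermost five nucleotides (position 1 = the terminal
base), weighted by reads (default) or uniquely per species, with log2
enrichment against the full-sequence background composition. Replicate
correlation is Pearson's r on log2(count+1) over the union of species
(absent = 0); the log transform is this package's choice. Top-N overlap
uses n as the denominator (a union/Jaccard variant is selectable).

## Differential expression

The reference pipeline this emulates used a negative-binomial framework;
here each species gets a **conditional exact binomial test**: given the
pooled count, the group-2 share is binomial with success probability equal
to the group-2 share of the total library size — the NB model with zero
dispersion under conditioning. This is self-contained and
oracle-checkable; numerical equality with NB tools is not claimed, and the
Monte-Carlo calibration test (null p < 0.05 fraction in [0.03, 0.07])
documents its behaviour. log2 fold change uses a prior count of 0.5 on
mean CPM. Benjamini–Yekutieli adjustment (BH with the harmonic factor
c(m) = Σ 1/k, valid under arbitrary dependence) is delegated to
statsmodels and verified in tests against a direct transcription of the
step-up formula. Calls are two-sided (|log2FC| ≥ 2 and adjusted
P < 0.01) — the threshold sentence reads one-sided but volcano displays
are symmetric — and species with mean raw reads < 2 are excluded.

## TE-qPCR estimator

See the README for the closed form. Implementation notes:

- **Censoring.** A treatment with no detectable template is censored at
  Ct 40. A censored vehicle (or AP) Ct is treated as detectable fraction 0;
  a censored T4 Pnk Ct means no template at all and is an error. This makes
  the estimator exactly invertible on the whole fraction simplex,
  including boundary points — verified on the 66-triple 10%-step grid.
- **Clamping.** Under Ct noise an intermediate fraction can go negative
  (e.g. AP Ct drifting above vehicle drives P% < 0). Default policy clamps
  negatives to 0 and lets OH% absorb the remainder so the sum is exactly
  100; `clamp=False` exposes the raw values for auditing.
- **Replicates.** Cts are averaged per treatment before inversion
  (averaging fractions instead differs at second order in the noise); a
  bootstrap over replicate triples supplies a dispersion estimate.
- **Efficiency.** The printed closed form assumes perfect doubling; a
  generalised-efficiency mode replaces 2 with E throughout.

## Slicer-site prediction

The duplex aligner replaces a thermodynamic tool with an exhaustive
antiparallel complementarity scan — exact and adequate for ≤ 40-nt
fragments. The register maximises Watson–Crick pairs (G:U only with
`allow_gu`; the validated duplexes are Watson–Crick at the relevant
positions, so wobble is off by default); ties prefer the longest
contiguous run of paired seed positions (guide 2–8), then the smallest
target offset. Fewer than 7 paired seed positions flags a weak duplex.
Cleavage requires a guide of ≥ 11 nt with positions 10 and 11 paired; the
cut falls between the target bases paired with those positions, so the
guide-side flanks are (10, 11) whenever prediction succeeds, and the
reported target cut index is the length of the 5′ product. The guide's
3′-end chemistry is metadata only — it never moves the site. Cleavage
kinetics are not modelled.

## The simulator: what it does and does not emulate

Emulated: read layout (insert + barcode + adapter), the chemistry routing
including periodate dropout of 3′-P species, per-chemistry ligation
efficiency acting at read-sampling time, the 3 × 3 spike-in panel with
10-fold steps, log-normal species abundances, uniform 15–30 nt lengths,
pyrimidine|purine 3′-end bias for cP species (default 0.95; a precursor
with no such junction falls back to an unbiased draw and is flagged),
per-base substitution errors, and a configurable fraction of low-quality
reads (default 2% at Q20, the rest Q37).

Not emulated: PCR duplicates, UMIs, indel sequencing errors (an optional
concern deliberately left out to keep the classifier oracle exact),
sequencer-specific quality profiles, and real reference databases — toy
tiers are random sequences, so passing tests demonstrate correctness of
the computations, not biological recall on real genomes. Spike-in
sequences are synthetic stand-ins; only the panel structure matters to any
computation. Species are screened so their sequences do not occur exactly
in a higher-priority tier, making the source tier the classification
ground truth.

Default problem sizes used by the test-bed runs — 150–200 species, read
depths of 2 × 10⁴ to 10⁵, two conditions × two replicates — are desk-scale
choices that keep every stochastic check well-powered (binomial/Poisson
tolerances at 5σ, 99% CIs) while the whole suite stays fast.

## Numerical and degenerate-input choices

- Determinism everywhere: every random draw flows from an explicit seed;
  classification caches per unique sequence and is read-order invariant.
- Zero-depth simulation, empty species tables and empty FASTQ inputs
  produce empty, well-formed outputs and a zero-count manifest.
- Zero-count libraries are an error in CPM normalisation; both-zero
  pooled counts give (log2fc 0, p 1).
- Alignment ties and name-rank ties are broken lexicographically so that
  all tables are stable across platforms.
- FASTQ parsing normalises U→T and uppercases at ingest; all internal
  comparisons are in the DNA alphabet.

## Known limitations

- The exact test ignores biological overdispersion; with many replicates
  it will be anticonservative relative to NB models. The BY adjustment
  partially compensates at the FDR level (and is itself conservative).
- Barcode demultiplexing discards reads with any barcode error; with the
  default 6-mer pair this is a sensitivity cost only.
- The duplex aligner has no thermodynamics; near-tie registers with
  equal pair counts are resolved structurally, not energetically.
- Mean-quality filtering is a simplification of qualified-base filtering;
  both rules are exposed, results on real data may differ between them.
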