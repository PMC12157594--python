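# Methods

`pancall` is a desk-scale re-implementation of pangenome-aware small-variant
calling: a caller that classifies candidate variants from short-read
alignments using pileup images augmented with a block of pangenome
haplotypes, so that population haplotype structure — not just the reads —
informs each genotype call. This note documents the model, the parameters
that matter, the synthetic data the package is validated on, and the design
choices made where more than one reasonable convention exists.

## The calling model

**Candidate discovery.** Reads aligned to a linear reference are scanned
per column; every (position, alternate allele) asserted identically by at
least `min_support` reads (default **2**) becomes a candidate. Indels are
anchored on the preceding reference base and left-aligned, so candidate
keys already follow the VCF convention and match truth records after the
same normalization. An optional fraction-of-depth threshold
(`min_fraction`, default 0 = off) exists because a pure count rule admits
noise at very high depth; it is off by default. Sites are kept biallelic
(`max_alts_per_site=1`, highest support wins) so the genotype label space
stays {homozygous-reference, heterozygous, homozygous-alternate}.

**Pileup tensors.** Each candidate becomes a tensor of shape
(2 × `height_per_block`, `width`, 6) = (200, 221, 6) by default: a window
of 221 reference columns centered on the candidate, a haplotype block of
100 rows stacked on top of a read block of 100 rows. The six channels are
the aligned base, base quality (capped at Q40), mapping quality (capped at
Q60), strand, support-for-the-candidate-alt, and differs-from-reference.
Channel values are fixed, monotone encodings in [0, 1]:

| channel | values |
|---|---|
| BASE | A 0.25, C 0.50, G 0.75, T 1.00, deletion gap 0.10, N 0.05, uncovered 0 |
| BASE_QUAL | min(q, 40)/40 |
| MAP_QUAL | min(q, 60)/60 |
| STRAND | forward 0.5, reverse 1.0 |
| SUPPORTS_ALT | carries alt 1.0, carries ref 0.5, other allele 0.25 |
| DIFFERS_FROM_REF | differs 1.0, matches 0.3 |

Quality and strand channels are identically zero in the haplotype block:
panel haplotypes carry neither. SUPPORTS_ALT and DIFFERS_FROM_REF *are*
populated for haplotypes because both are computable from the alignment
alone; the haplotype-block SUPPORTS_ALT column fraction at the candidate
is exactly the panel allele frequency, which is the signal the model is
meant to exploit. Insertions are encoded at their anchor column (the
window is in reference coordinates; columns are never expanded);
deletions render as the gap code. Reads are sorted by (start, name), so
the tensor is invariant to input read order; if more reads overlap the
window than the block height, a seeded uniform subsample of exactly
`height_per_block` reads is used. A panel larger than the block is an
error by default — the sanctioned remedy is haplotype sampling — with an
opt-in seeded subsample.

Tensors are stored as float16: every encoding above is coarse by design,
and example sets dominate memory at scale. Training casts each minibatch
to float32.

**Genotyper.** A compact CNN maps the tensor to probabilities over
{REF, HET, HOM_ALT}: three conv blocks (8/16/32 filters, 3×3 kernels,
strides 3/2/2, ReLU), then a mean over the *row* axis only, then a dense
layer (64) and softmax. Pooling rows but not columns is deliberate: rows
are an unordered population of reads/haplotypes whose aggregate statistics
matter, while the column axis carries the positional signal centered on
the candidate. Because haplotype rows are identifiable by their zeroed
quality channels, row-mean features still separate haplotype statistics
from read statistics. The stride-3 first layer and the small filter counts
size the network for single-CPU training in minutes; the function class is
deliberately minimal, not a reproduction of any production architecture.

Training uses softmax cross-entropy with inverse-frequency class weights
(REF candidates dominate), Adam (learning rate 3e-3), batch size 64, up to
10 epochs with early stopping (patience 3) on holdout loss. Examples on
the held-out contigs are excluded from gradient updates and serve as the
validation set — the held-out-chromosome convention; without a holdout a
seeded 10% split is used. All randomness (initialization, shuffling,
dropout) derives from one config seed; training is bit-reproducible on a
given platform, and checkpoints (weights + config + shape/channel
descriptor) reproduce predictions bitwise.

**Calls and VCF.** Genotype is the argmax class; ties within 1e-9 resolve
conservatively REF > HET > HOM_ALT. GQ = min(99, round(−10·log10(1−p_max)))
with p_max clipped below 1, QUAL set equal to GQ, and homozygous-reference
outcomes written as RefCall (excluded from the VCF unless requested).
DP/AD come from the candidate's depth and support counts.

## Haplotype sampling (personalized panels)

Sample reads are reduced to canonical k-mers (k = 29, strand-neutral,
`min_count` = 2 to suppress error k-mers). Each panel haplotype is split
into non-overlapping 10 kb segments and each segment scored by containment:
the fraction of its distinct canonical k-mers present in the read set.
Segmenting lets similarity vary along a haplotype, which approximates
recombination between segments (not within one). A haplotype's aggregate
score is the mean of its segment scores; the top-N haplotypes (N = 16, 32
or 64 in the calling pipeline, any N works) form the personalized panel.
The containment fraction is this package's own scoring rule; it uses the
same inputs and granularity as k-mer–based haplotype samplers but does not
construct per-segment mosaics.

## Benchmarking and error transitions

`compare_to_truth` joins PASS calls against truth on the normalized
(contig, pos, ref, alt) key inside the confident regions. A key match with
a genotype mismatch counts as one FP *and* one FN, so precision and recall
both register the error. Entries are genotype-qualified keys
(…, called-genotype for FPs, truth-genotype for FNs); this makes TP/FP/FN
and all transition sets well-defined and the four transition categories —
removed FP, rescued FN (fixed errors), induced FP, induced FN (introduced
errors), computed as set differences between a baseline run and a
pangenome-aware run against the same truth — pairwise disjoint by
construction. There is no haplotype-equivalence matching (vcfeval-style):
the synthetic generator emits non-overlapping normalized variants, for
which exact matching is lossless; parity with hap.py on real data is a
non-goal. Transitions default to SNPs only, the class that dominates
pangenome-driven improvements. Counts stratify by a labelled region
partition (duplication-identity classes vs rest, rates per Mb), by
adjacent 100 kb windows, and by panel allele frequency in bins of width
0.2 (last bin closed at 1.0; alleles absent from the panel get frequency 0
and are flagged).

## The synthetic data generator

The generator emulates the regime the method targets, not a full
sequencing instrument:

* **Reference**: uniform-random A/C/G/T contigs carrying a duplication —
  a destination segment copied from a source segment with substitution-only
  divergence (identity 0.99 by default). High-identity duplicated sequence
  is where short reads mismap for lack of unique markers and where
  pangenome context should help most.
* **Panel**: variant sites on a spaced grid (≥ 8 bp apart, so exact
  diffing and normalization are unambiguous); 90% SNVs, 10% indels of
  1–5 bp (small variation is SNV-dominated); per-haplotype variant density
  1e-3/bp (the order of human heterozygosity); carrier counts drawn with
  P(i) ∝ 1/i, a neutral-spectrum-like law that concentrates mass at low
  frequency and makes the 0.2-wide frequency bins monotonically decreasing.
* **Diploid sample**: each haplotype copies one panel donor and adds
  private variants at 5e-5/bp — most sample variation exists in the panel,
  some does not.
* **Reads**: single-end 100 bp (pairing adds no behaviour this caller
  exercises), uniform coverage, per-base substitution errors at 1e-3 with
  base quality 12 at error positions (35 elsewhere). Reads lying entirely
  inside one duplication copy are re-addressed to the homologous copy with
  the mismap probability (mapping quality 2, sequence kept) — they present
  as dense mismatch clusters at the wrong locus, the reference-bias
  signature the haplotype block is meant to resolve.
* **Truth**: the exact diff of the sample haplotypes against the
  reference, phased, restricted to confident regions (whole contigs minus
  a short edge margin), plus a labelled partition BED for stratification.

Presets: `small` (2 × 500 kb contigs, panel 20, 30×, 8% of each contig
duplicated, mismap 0.25) is the end-to-end training/calling condition;
`biased` (2 × 80 kb, panel 20, 25×, half of each contig duplicated, mismap
0.35) concentrates the mismapping regime for the ablation comparison;
`tiny` (1 × 30 kb, panel 8) is for fast tests. Sizes were chosen so a full
train/call/benchmark cycle runs in minutes on one CPU while leaving
hundreds of candidate sites per contig.

What the generator does **not** model: instrument-specific error profiles,
indel sequencing errors, paired-end structure, coalescent genealogies,
recombination within the sample haplotypes (each copies a single donor),
and overlapping variant representations. Consequently, passing tests show
that the method's machinery — discovery, encoding, learning, calling,
benchmarking — behaves as documented and that the haplotype block carries
exploitable signal under reference bias; they do not certify accuracy on
real sequencing data.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere; 1-based appears only in
  VCF serialization and on the command line.
* Variant normalization = trim shared trailing bases, left-extend through
  homopolymers, trim shared leading bases beyond the anchor.
* Reads with mapping quality 0 are retained — they carry exactly the
  mismapping signal the method is designed to see through. `=`/`X` CIGAR
  ops normalize to M; hard clips are dropped; duplicates are not flagged
  by the simulator and not filtered.
* The discovery depth at a column counts reads spanning it with an
  aligned base or deletion; soft clips assert nothing.
* Ablation baseline ("linear-reference" model) = identical architecture
  and training on the same tensors with the haplotype block zeroed, so the
  comparison isolates the information content of the haplotype block.
* The panel ingest contract is haplotype-to-reference alignments (SAM) or
  a phased multi-sample VCF; graph formats and graph topology operations
  are out of scope, as are gVCF output, multiallelic genotypes, CRAM, and
  read mapping itself.

## Known limitations

* Exact-key matching will under-credit equivalent-but-differently-
  represented calls on real data; use hap.py/vcfeval there.
* The CNN is sized for desk-scale example sets; it is not expected to be
  competitive with production callers trained on whole-genome truth sets.
* Haplotype sampling scores whole haplotypes (mean over segments); it
  does not build recombinant mosaics, so a panel with no single good
  donor match may score poorly even when a mosaic would fit.
* The phased-VCF panel path requires split multiallelic records and
  non-overlapping variants per haplotype.
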