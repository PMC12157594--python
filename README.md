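# pancall

Pangenome-aware small-variant calling at desk scale.

Short-read variant callers that look only at reads mapped to a linear
reference suffer from *reference bias*: where the sample diverges from the
reference — most dramatically in high-identity segmental duplications —
reads mismap and calls go wrong. `pancall` implements the idea of feeding
a *pangenome* (a panel of assembled haplotypes aligned to the same linear
reference) directly into the genotyper: every candidate variant becomes a
fixed-width pileup image in which a block of panel haplotypes is stacked
on top of the read block, and a convolutional network classifies the
candidate as `0/0`, `0/1` or `1/1`. Population haplotype structure then
acts as a learned prior that separates true variant signal from mapping
and sequencing noise.

The package is a complete, testable laboratory for this method on
synthetic diploid genomes: it generates references with near-identical
duplications, phased panels with a realistic allele-frequency spread,
error-bearing and occasionally mismapped reads with an exact truth VCF;
it discovers candidates, encodes pangenome-augmented pileup tensors,
trains and applies the CNN genotyper, emits VCF, builds *personalized*
panels by k-mer similarity (haplotype sampling), and benchmarks call sets
— including the "errors fixed vs errors induced by the pangenome"
dissection, stratified by duplication identity, genomic windows and panel
allele frequency.

## The method in brief

* **Candidates**: any position where ≥ 2 reads assert the same mismatch
  or indel (indels anchored and left-aligned, VCF-style).
* **Pileup tensor**: 221 reference columns centered on the candidate ×
  (100 haplotype rows + 100 read rows) × 6 channels (base, base quality,
  mapping quality, strand, supports-alt, differs-from-reference); quality
  and strand channels are blank for haplotypes. The haplotype-block
  supports-alt fraction at the center column *is* the panel allele
  frequency of the candidate allele.
* **Genotyper**: a compact CNN (three strided conv blocks, row-mean
  pooling that preserves the column axis, dense softmax head) trained
  with a held-out contig for validation; `GQ = min(99, −10·log10(1−p))`.
* **Haplotype sampling**: canonical 29-mers from the reads score each
  haplotype in 10 kb segments by containment; the top-N haplotypes (16,
  32, 64, …) form a personalized panel.
* **Evaluation**: exact-key benchmarking inside confident regions;
  between a baseline and a pangenome-aware call set the four transition
  categories *removed FP*, *rescued FN*, *induced FP*, *induced FN* are
  set differences, counted per region class (per Mb), per 100 kb window
  and per 0.2-wide panel-allele-frequency bin.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

```python
import numpy as np
from pancall import simulate_biased_scenario, ModelConfig, train, predict
from pancall.pipeline import (discover_bundle_candidates, build_labelled_examples,
                              call_variants, evaluate_calls, macro_f1)

bundle = simulate_biased_scenario(seed=7, preset="small")   # 2 x 500 kb, panel 20, 30x
cands  = discover_bundle_candidates(bundle)
ex     = build_labelled_examples(bundle, cands)
model  = train(ex, ModelConfig(seed=7), holdout_contigs=["contig2"])

test  = [e for e in ex if e.candidate.contig == "contig2"]
pred  = np.array([p.as_array().argmax() for p in predict(model, test)])
truth = np.array([e.label for e in test])
print("macro F1 (het/hom):", round(macro_f1(truth, pred), 4))
res = evaluate_calls(bundle, call_variants(model, test), contigs=["contig2"])
print("precision", round(res.precision, 4), "recall", round(res.recall, 4),
      "errors", res.total_errors)
```

prints (seed 7):

```
macro F1 (het/hom): 0.9768
precision 0.977 recall 0.977 errors 38
```

i.e. on the held-out contig the model recovers heterozygous and
homozygous genotypes with macro-F1 0.98 and calls variants at 97.7%
precision / 97.7% recall, leaving 38 errors among ~1700 candidate sites.
Zeroing the haplotype block and retraining the identical network (the
linear-reference baseline) raises the error count substantially — that
difference, dissected into fixed and induced errors, is what the
evaluation module quantifies. The `examples/` scripts walk through each
capability one at a time and print what every number means.

There is also a thin CLI mirroring the pipeline stages
(`pancall simulate | make-examples | train | call | sample-haplotypes |
evaluate | error-transitions`); run `pancall --help`.

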