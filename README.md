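# exocnv

Exon-level copy-number-variant (CNV) calling from read depth for
low-coverage, degraded genomes — the regime typical of ancient DNA (aDNA),
where conventional read-depth CNV callers break down below ~1× coverage.

## Who this is for

Researchers in archaeogenetics / paleogenomics who have coordinate-sorted
alignments (or per-base depth tracks) of low-coverage samples, an exon
annotation, and access to CNV calls from a conventional caller on a few
*high*-coverage samples, and who want exon- and gene-level DEL/DUP calls on
the low-coverage material.

## The method

Each exon `X_i` (≤ 1 kbp; longer exons are discarded) is represented by its
per-base read depth, divided by the sample's mean per-base depth and
right-padded with zeros to a 1000-position window. The classifier
`f(X_i, θ)` maps this window to probabilities over {NO-CALL, DEL, DUP}:

1. two 1-D convolutions (1 → 32 → 64 channels, kernel 3, stride 1), each
   followed by batch normalization and ReLU, giving an embedding in
   R^(1000×64);
2. a trainable **chromosome-specific classification token** c_t ∈ R^64 is
   appended (sequence length 1001) and a sinusoidal positional encoding is
   added;
3. a cascade of three transformer encoder blocks transforms the sequence
   shape-preservingly; the token position is sliced out and a fully
   connected head with softmax yields the class probabilities; the argmax
   is the call (exact ties fall back to NO-CALL).

Training is two-stage. The model is first **pretrained** on windows whose
labels come from a conventional caller run on high-coverage data. It is
then **fine-tuned** on pairs of (binomially coverage-thinned window,
full-coverage label) — Adam, cosine-annealed learning rate (full-scale
default 5 × 10⁻⁵) — which teaches it to recognize the same events in the
sparse, spiky depth signal of 5×…0.05× data. Exons with no aligned reads
at all (~5% in degraded samples) are resolved afterwards by majority vote
over the three nearest called exons on the same chromosome, and gene-level
calls by majority vote over each gene's exons.

A bundled synthetic generator (toy exome, planted DEL/DUP events, negative
binomial depth ∝ copy number, contamination noise, coverage ladder,
frequency-structured multi-sample deletion cohorts) supports desk-scale
training experiments and the population-genetic analyses (deletion matrix,
PCA, silhouette, Manhattan/Ward-D2 hierarchical clustering, site frequency
spectrum, deletion-size spectrum).

## Worked example

```python
import numpy as np
from exocnv import (ExonCNVClassifier, SyntheticConfig, make_toy_exome,
                    generate_sample, windows_from_depths, confusion_and_f1)
from exocnv.benchmark import synthetic_recovery

result = synthetic_recovery(seed=0)
print({k: round(v, 3) for k, v in result.items() if k.startswith("macro")})
```

prints

```
{'macro_f1_moderate': 0.894, 'macro_f1_low_baseline': 0.071,
 'macro_f1_low_finetuned': 0.281}
```

i.e. on a held-out synthetic sample pair the reduced-scale model reaches
macro-F1 0.89 (mean of DEL and DUP one-vs-rest F1) at 1×-equivalent
coverage; evaluated cold at 0.05×-equivalent coverage it collapses to
0.07, and fine-tuning on 0.05×-thinned windows recovers it to 0.28 —
the coverage-robustness mechanism the two-stage training exists for.
(At 0.05× an exon window holds only ~5 reads, which bounds what any
read-depth method can achieve there.)

The same workflow is available from the shell:

```sh
exocnv simulate --out-dir sim --n-samples 3 --seed 0
exocnv train    --exons sim/exons.bed --manifest sim/manifest.tsv \
                --calls-dir sim --checkpoint model.npz --seed 0
exocnv finetune --exons sim/exons.bed --manifest sim/manifest.tsv \
                --calls-dir sim --checkpoint model.npz --fractions 0.1,0.05 \
                --out tuned.npz --seed 0
exocnv call     --checkpoint tuned.npz --depth sim/sim1.x0.05.depth.tsv.gz \
                --exons sim/exons.bed --out calls.tsv --gene-out genes.tsv
exocnv popstats --calls calls.tsv --calls calls2.tsv --exons sim/exons.bed \
                --groups groups.tsv --out popstats.json
```

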