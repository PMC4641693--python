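# mirloc

Locating the **mature miRNA** within a plant **pre-miRNA hairpin**.

Plant microRNAs (~21 nt) are excised from hairpin-structured precursors
(pre-miRNAs). Computational miRNA discovery pipelines are good at finding
the hairpins, but predicting *where inside the hairpin* the mature strand
sits is the harder problem: each pre-miRNA offers hundreds of plausible
~16–30 nt segments, of which exactly one is the functional guide strand.
`mirloc` solves this as a machine-learning problem over miRNA:miRNA\*
duplexes, for researchers annotating miRNAs in model and non-model plant
genomes.

## Method

1. **Fold** each pre-miRNA (ViennaRNA; MFE structure + partition-function
   base-pair probabilities `p_ij`).
2. **Derive the duplex** for a candidate guide interval: the star strand is
   traced through the pair table from the partners of the outermost paired
   guide bases, plus a 2-nt 3′ overhang.
3. **Encode** each duplex as a fixed 440-dimensional vector: 197 sequence
   properties (length, mono/di-nucleotide frequencies, one-hot ±5-nt context
   at duplex strand boundaries), 30 structural properties (duplex MFE, base
   pair counts and windowed densities, perfect-pair runs, bulge/loop counts,
   distances to terminal loop and stem base, ±3-nt bulge flags), 22
   positional entropies H(i) = −Σ q log₂ q of the pairing state at ±5 nt
   around the guide ends, and 191 sequence×structure combination counts
   (monoSSq, diSS, collapsed-bracket triplets).
4. **Train** a classifier (random forest by default; SVM/NB/kNN/DT
   available) on annotated guides (positives) versus random same-length
   segments of the same hairpins (negatives) at a chosen positive:negative
   ratio (RPNS, default 1:5). Performance is measured by grouped,
   stratified 10-fold cross-validated AUC.
5. **Locate**: every candidate (start `p`, length `16 ≤ L ≤ 30`) is scored;
   the predicted start maximises the summed score

   S(p) = Σ<sub>16≤L≤30</sub> score(p, L),

   and the predicted length maximises score(p_pred, L). Accuracy is
   reported as the cumulative fraction of predictions whose start (end)
   falls within d nt of the truth, for resolutions d = 0…10.

A seeded synthetic-hairpin generator (random 5′ arm + loop + perturbed
reverse complement, with a planted guide) makes the whole pipeline testable
without any external database.

## Worked example

```bash
python examples/03_train_and_locate.py
```

simulates 120 annotated hairpins, trains on 90, and locates the mature
miRNA in the 30 held-out hairpins:

```
training set: 90 positives, 450 negatives (RPNS 1:5)
10-fold CV mean AUC: 0.978 (folds 0.941-1.000)
top features by Gini importance: dist2Loop (0.066), dist2Helix (0.042), posEntropy_end_d3 (0.037), ...

localization on 30 held-out hairpins:
  d=0: start accuracy 0.13, end accuracy 0.27
  d=3: start accuracy 0.70, end accuracy 0.93
  d=5: start accuracy 0.83, end accuracy 1.00
```

The AUC says the forest separates real duplexes from pseudo-duplexes
almost perfectly; the d-resolution curve says 83% of predicted start
positions land within 5 nt of the planted guide. `examples/01_*.py` and
`02_*.py` walk through folding/entropy and duplex featurization.

The same pipeline runs from the shell:

```bash
mirloc simulate --n 200 --seed 1 --out-prefix corpus
mirloc train    --fasta corpus.fa --annotations corpus.annotations.tsv \
                --rpns 5 --folds 10 --seed 1 --model-out model.joblib --cv-out cv.json
mirloc predict  --model model.joblib --fasta corpus.fa --out predictions.tsv
mirloc evaluate --predictions predictions.tsv --truth corpus.annotations.tsv --out curves.tsv
```

Real data enter through the same interfaces: a FASTA of pre-miRNAs (DNA is
auto-converted T→U), an annotations TSV (`premirna_id  mirna_seq` or
`premirna_id  start  end`, 1-based inclusive), and optionally a Vienna
dot-bracket file via `--structures` to bypass folding.

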