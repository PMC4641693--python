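# Methods

## Problem and model

Given a pre-miRNA hairpin, `mirloc` predicts the interval of the mature
miRNA (guide strand). The model is a binary classifier over miRNA:miRNA\*
duplex candidates: a candidate is the duplex formed by a 16–30 nt guide
interval and its star strand read off the folded secondary structure.
Training positives are duplexes anchored at annotated mature miRNAs;
negatives are pseudo-duplexes anchored at random segments of the same
length in the same hairpin. At prediction time every candidate (p, L) is
scored with the positive-class probability and the guide is placed at the
start maximising the summed score S(p) = Σ_L score(p, L), with length
argmax_L score(p_pred, L). Ties break toward the smaller start, then the
smaller length.

Assumptions: each input is a single hairpin (multi-branched structures are
rejected with `MultiBranchStructure`); exactly one mature miRNA is emitted
per pre-miRNA; the folded MFE structure is a usable proxy for the in-vivo
structure.

## Coordinates and alphabets

Internally all intervals are 0-based half-open; every user-facing table and
`Prediction` uses 1-based inclusive coordinates. Sequences are normalised
to uppercase RNA on input (T→U); N is accepted but never pairs and routes
combination features to their "undefined" buckets.

## Folding

The default engine is ViennaRNA (MFE structure plus partition-function
base-pair probability matrix, `p_ij`). Engines are pluggable behind a small
contract (`mfe_structure`, `partition_function`, `duplex_energy`
capabilities; deterministic within one engine version; name+version
recorded in outputs). The bundled fallback is a maximum-base-pairing
(Nussinov) folder with minimum loop 3 and canonical+wobble pairs; it is
non-thermodynamic, reports the surrogate energy −(3·GC + 2·AU + 1·GU), and
exists so the test suite has an exactly checkable oracle — it is not a
substitute for a nearest-neighbour folder.

## Positional entropy

The pairing uncertainty of position i is the Shannon entropy over the
outcome set {pair with j}_j ∪ {unpaired}, the last outcome carrying mass
1 − Σ_j p_ij:

    H(i) = − Σ_k q_k log2 q_k .

This form is 0 at any point mass and log2(n) for a uniform spread over n
partners — the two endpoints the feature is defined by. (A published
variant wraps an outer log2 around summed per-partner binary entropies;
that expression diverges to −∞ at p = 1 and cannot reach the stated
endpoints, so the Shannon form is implemented.) When only an MFE structure
is available (no partition function, e.g. structures supplied via
`--structures`), a degenerate point-mass matrix is synthesised so entropy
features are defined — they are then all 0 — and a warning is emitted.
Models trained with partition-function entropies and applied to
MFE-only inputs therefore see a feature-distribution shift; prefer
matching modes between training and prediction.

## Duplex derivation

There is no single agreed definition of the star strand in the field;
`mirloc` uses outermost-pair tracing: the star spans the partners of
the first and last paired guide bases, extended by a 2-nt 3′ overhang (the
Dicer-product convention), truncated at the sequence end and at the guide
boundary. Guide pairs closing back into the guide itself (a candidate
spanning the terminal loop) are ignored for star derivation; a candidate
with no pair outside itself raises `NoPairedBases` and simply contributes
no score during prediction.

Element definitions (classic duplex anatomy): walking consecutive duplex
base pairs, an unpaired run on exactly one strand is a **bulge**, unpaired
runs on both strands form one **internal loop**; the terminal loop is never
counted. `mlBulge` is the longest consecutively paired guide run.
`dist2Loop` is the gap between the loop-proximal guide end and the terminal
loop; `dist2Helix` the gap between the other guide end and the hairpin's
outermost paired base ("start of the helix" read as the stem base — the
phrase is ambiguous and this reading is fixed here).

Duplex free energy uses the engine's two-strand refold
(`RNA.duplexfold`) of guide and star; without a capable engine the
surrogate above is used and is visible in the engine metadata. A zero-pair
duplex scores 0.0 by convention.

## The 440-feature schema (`mirloc-440-v1`)

Group sizes: miRNALen 1, MNC 4, DNC 16, NT5p 88, NT3p 88, MFE 1, mlBulge 1,
bpNum 1, dist2Loop 1, dist2Helix 1, numLoop 1, numBulges 1, perfectBP 3×2,
numBP_Win 3, Bulges 7×2, posEntropy 11×2, monoSSq 13, diSS 145,
triplets 33 — totalling 440 (197 sequence + 30 structural + 22 entropy +
191 combination).

Decisions where the layout was genuinely open:

* **NT blocks** are anchored on the duplex's 5p and 3p *strands* (which is
  the star when the guide lies on the 3′ arm), while posEntropy and bulge
  flags anchor on the *guide* start/end — matching how the feature
  catalogue names them.
* One-hot codes follow A=0001, C=0010, G=0100, U=1000 (bit columns stored
  U,G,C,A); out-of-window positions and N encode as all-zero. Out-of-bounds
  entropy and bulge offsets encode as 0.
* **MNC/DNC** are frequencies (counts over L and L−1).
* **perfectBP** start positions are 0-based offsets from the guide start;
  the absent-run sentinel is (0, −1).
* **numBP_WinX** is the mean paired count over all length-X windows; a
  guide shorter than X contributes its single full-guide count.
* **triplets** use the collapsed-bracket alphabet (both brackets =
  "paired"; 4 nt × 8 patterns + undefined = 33 — the only reading whose
  arithmetic matches), while monoSSq and diSS keep '(' and ')' distinct,
  preserving informative bracket-specific states such as "U)".
* Counting identities hold by construction and are asserted per sample:
  Σ monoSSq = L, Σ diSS = L−1, Σ triplets = L−2.

`featurize` is pure: identical inputs give bit-identical vectors. The
schema version is embedded in datasets and models; a trained model refuses
feature input from any other schema version.

## Datasets

One duplex per pre-miRNA enters the positive set even when both arms are
annotated (the 5p-anchored duplex is kept; its star covers the 3p
annotation). A sequence-based annotation occurring multiple times resolves
to the occurrence with the most base pairs, ties leftmost. Negatives have
exactly the true miRNA's length and a start more than 2 nt from the true
start; they may otherwise overlap the true miRNA (distinctness at the
resolution the evaluation measures). Shortfalls on short hairpins are
logged, not raised. Default RPNS is 1:5; 1:1/1:10/1:50 are selectable.

Cross-validation folds are stratified by label **and grouped by
pre-miRNA**: a positive and its sibling negatives share hairpin-level
information (same fold ⇒ no leakage). Ungrouped splitting would inflate CV
AUC. Within the grouping constraint a greedy dealer balances positive
counts first, then totals, so class sizes differ by ≤1 when groups are
singletons.

## Classifiers

scikit-learn estimators behind a thin wrapper: random forest (500 trees,
√f features per split — defaults declared here, not taken from any source),
RBF-SVM (C=1, gamma="scale", standardised inputs, Platt-scaled
probabilities), Gaussian naive Bayes, kNN (k=5), decision tree. Every
hyperparameter is overridable via `params`. Class weights are deliberately
not rebalanced internally: imbalance is expressed through the sampled RPNS
only. AUC uses the Mann-Whitney rank formulation with half-credit ties,
identical to trapezoidal ROC integration over all distinct score
thresholds. Gini importances are sklearn's mean decrease in impurity,
normalised to sum to 1 and reported with 1-based ranks.

Models persist as a joblib artifact with an embedded JSON header
(algorithm, params, schema_version, seed, training counts, format_version);
loading fails loudly (`CorruptModelFile` / `SchemaMismatch`) on truncation
or version mismatch.

## Locator

Candidates are every (p, L) with 16 ≤ L ≤ 30 and p+L ≤ n, enumerated start-
ascending then length-ascending. Starts near the 3′ end admit fewer lengths
and hence a downward-biased raw S(p); the sum is intentionally left
unnormalised (faithful to the summed-score definition) and the bias is
noted here rather than corrected. Candidates without a derivable duplex are
skipped (score 0). Localization quality is the cumulative fraction of
predictions within d nt of the truth, d = 0..10, reported separately for
starts and ends; both curves are non-decreasing by construction.

## Synthetic generator

`generate_hairpin` emulates a plant pre-miRNA: a uniform-random 5′ arm
(default 40 nt; corpus draws 35–45), a random terminal loop (8 nt; corpus
6–10), and the arm's reverse complement perturbed per position by
Bernoulli(bulge_rate) events, half mismatches and half single-nucleotide
insertions (default rate 0.05 ≈ one or two imperfections per arm, the
mild asymmetry typical of real miRNA duplexes). The guide (default 21 nt;
corpus 20–22) is planted in the 5′ arm with its 3′ end 1–4 nt from the
loop, mimicking the loop-proximal placement common for plant mature
miRNAs. Everything is deterministic given the seed.

What the generator does **not** emulate: 3′-arm guides (all planted guides
are 5p), multi-miRNA hairpins, genomic dinucleotide composition, G:U-biased
wobble structure, species-specific length distributions, and annotation
noise. Passing tests on this corpus therefore demonstrate that the
machinery is correct and that the locator recovers a planted signal under
realistic fold imperfection — not that any particular accuracy carries over
to real miRBase-style corpora, whose difficulty is higher.

## Problem sizes and numerics

The heavyweight acceptance checks use a 200-hairpin corpus (150 train / 50
held out, RPNS 1:5, bulge rate 0.05, 10-fold CV) — large enough for stable
AUC/recovery estimates while keeping the full suite in the minutes range on
a single CPU. Oracle equivalences run on 1000 random dot-bracket strings,
1000 random AUC instances, 500 random score grids, and ≤30-nt random
sequences against an independent maximum-pairing recursion. Probability
validation uses ε = 1e-6 on [0,1] bounds and row sums; bppm entries below
1e-12 are clipped to 0. Degenerate inputs: empty score grid →
`NoPrediction`; zero-pair duplex energy 0.0; unpaired structure has no
terminal loop and `dist2Loop`/`dist2Helix` fall back to 0.

## Known limitations

* Single-hairpin inputs only; one prediction per pre-miRNA.
* MFE-only mode zeroes all entropy features (see above).
* The star-strand 3′ overhang (2 nt) follows field convention; alternative
  conventions would shift NT(3p)/NT(5p) anchors by a base or two.
* The maximum-pairing fallback engine must not be mixed with
  thermodynamically trained models.
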