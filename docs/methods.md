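# Methods

This note documents the models and procedures promtok implements, the
defaults it ships, the numerical choices behind them, and what its tests
do and do not demonstrate.

## Synthetic promoter corpora

The generator produces, per organism, one chromosome over {A,C,G,T,N} and
a table of planted TSSs, emulating the statistical structure of curated
promoter collections:

* **Background**: a first-order (dinucleotide) Markov chain with CpG
  suppression (the C→G transition down-weighted to 0.2 before row
  renormalization). The stationary GC content starts at 0.41 for the
  reference organism and drifts by `gc_drift_rate × distance` (default
  1.5 × 10⁻⁴ per MYA-like unit, clipped to [0.25, 0.65]) so that
  compositional divergence increases monotonically with phylogenetic
  distance — the "shared regulatory language with organism dialects"
  structure the cross-species experiments probe.
* **Promoters**: TSSs are placed on a jittered grid that guarantees
  non-overlapping 601-nt windows (a capacity error is raised otherwise).
  Each promoter gets a mildly GC-enriched core (±50 nt, +0.06 GC), a
  TATA-box (`TATA[AT]A`, planted at a uniform offset in [−35, −25]) with
  probability `tata_fraction` = 0.129 — the prevalence the positive class
  is modelled on — and a fixed downstream hexamer (`GGACGT`) at +90 with
  probability `downstream_strength` = 0.9. The 0.9 default makes the
  downstream element a strong but not universal feature, enough for a
  tiny model to find it yet leaving honest class overlap; the +90 offset
  places it at window index 390, the position the attribution analysis is
  designed to resolve. Strands are random; minus-strand promoters are
  planted reverse-complemented so extraction recovers the same 5'→3'
  frame.
* **Redundancy**: `family_count` families of `family_size` near-duplicate
  promoters (member windows mutated at exactly ⌊(1−identity)·601⌋
  positions, identity default 0.9 > the 0.8 clustering threshold, so
  families must co-cluster). Family membership is returned for oracle
  tests.
* **Ambiguity**: `N` bases injected i.i.d. at 10⁻⁴ per base, never inside
  planted motifs.

All randomness flows through a single `numpy.random.Generator`; a fixed
seed reproduces chromosomes byte for byte.

What the generator does **not** emulate: indels and synteny, nucleosome or
CpG-island biophysics, realistic motif grammars, or the exact per-organism
promoter counts of any database. Passing tests demonstrate that the
pipeline's machinery is correct and recovers planted structure; they do
not certify real-data performance.

## Negative sets

*Shuffled*: 25 contiguous 24-nt segments tile positions 0..599; 8 chosen
uniformly without replacement are permuted in place; the 601st base and
all unchosen segments remain byte-identical, so the nucleotide multiset is
conserved exactly. The expected motif retention formula
`p · (n_segments − n_perturb)/n_segments` follows from a motif surviving
iff its segment is untouched (boundary-straddling motifs are ignored; at
12.9% prevalence the difference is below measurement noise at n = 2000).
An i.i.d.-substitution mode exists behind a flag for sensitivity analysis.
A known consequence of the design: any class feature concentrated at a
fixed position (TATA at −30, the downstream element at +90) survives in
~68% of negatives, making shuffled-negative tasks partly *order*-dominated
rather than composition-dominated.

*Fragment*: negative TSSs are drawn uniformly on the paired positive's
chromosome and accepted only if ≥ 600 nt from every positive and every
previously accepted negative TSS (distances between TSS coordinates, not
window edges, so adjacent windows may touch at exactly 600 — accepted as
designed). After `max_tries` = 1000 rejected draws the record is skipped
and logged, leaving an explicit imbalance rather than a silently relaxed
constraint.

## Clustering and the accumulation split

Identity is ungapped Hamming identity over equal-length windows (`N`
matches nothing) — a deliberate simplification of word-filtered banded
alignment; `.clstr` import provides the faithful alternative. Greedy
clustering processes sequences in deterministic order (length descending,
id ascending) and joins the first representative at ≥ 80%; an
overlapping-6-mer fingerprint prefilter skips hopeless comparisons
(heuristic, but pairs at ≥ 80% identity share many hexamers in practice).

The split sorts clusters by size ascending and assigns whole clusters to
test until its 20% target is reached, then validation (15%), then train.
Ties in cluster size break on a stable hash of the representative id:
still a pure function of the input, but interleaving organisms — a
representative-id-lexicographic tie-break would funnel entire organisms
into single partitions at small corpus sizes. A cluster that crosses a
target boundary stays whole in the set being filled, which is why achieved
fractions deviate slightly from the targets. Degenerate inputs (one giant
cluster) go wholly to test with a warning.

## Tokenizers

BPE merges the globally most frequent adjacent pair; the WordPiece-style
trainer merges the pair maximizing `count(ab)/(count(a)·count(b))`; both
start from single characters, never merge across sequence boundaries,
exclude any pair touching `N` (so no multi-character token ever contains
`N`), break ties to the lexicographically smallest pair, and stop at a
target content-vocabulary size or when no pair occurs twice (WPC: when the
best pair's raw count falls below `min_pair_count`). Inference replays
merges by rank (BPE) or greedy longest-prefix matching with `[UNK]`
fallback (WPC). k-mer vocabularies enumerate all 4^k unambiguous k-mers
plus observed N-containing ones. Every encoder returns half-open
nucleotide spans per token; the non-overlapping k-mer's dropped tail
(position 600 at k = 6) is recorded and later treated as missing, not
zero.

## Encoder and training

The model is a pre-norm transformer encoder written directly in numpy
(explicit forward/backward, Adam) — desk-scale by default (2 layers, 64
hidden, 4 heads) with every size in `EncoderConfig`. Masked-LM
pretraining uses the standard 15% selection with 80/10/10
mask/random/keep corruption and consumes *positive* windows only (a hard
contract, enforced). Curricula are per-epoch organism subsets: flat (all
organisms every epoch) or evolutionary-informed (all organisms for epochs
1..switch, then the target's 4 nearest relatives, target included; an
epoch is one pass over the union of the scheduled organisms' sequences,
so the flat arm sees roughly twice the observations after the switch).
Classification reads a `[CLS]` token prepended at encoding time (excluded
from positional spans), trains with binary cross-entropy, batch size 8,
Adam, and early-stops on validation loss (patience 3) restoring the best
epoch. Given a seed, loss traces are bit-identical across runs on the
same platform; predictions are independent of batching because attention
masks padded keys and nothing else mixes positions.

A caveat established empirically with this implementation and documented
because it shapes the tests: at desk scale, warm-starting from a
pretrained state *slows* convergence on tasks a near-linear model can
solve from token composition alone (the scratch model exploits its
near-identity initialization faster than the pretrained one restructures).
The pretraining benefit is real and large precisely where the class signal
lives in token *order* — e.g. positives with coherent local structure
versus negatives with the same token multiset shuffled — which is the
regime the transfer test exercises.

## Attribution

For a trained classifier, token scores are computed on the probability
scale (bounded, comparable across models): occlusion
(`P(x) − P(x with token t → [MASK])`, the dependency-free default) or a
Monte-Carlo permutation Shapley estimate with the `[MASK]` token as
background. Scores are broadcast onto the nucleotides each token covers
(mean where overlapping tokenizers cover a position with several tokens;
uncovered positions are missing and excluded from averaging), then
averaged across the selected windows — by default the 100 test records
most confidently predicted for the class, ties broken by id. The result
is a length-601 profile indexed by TSS offset; the negative-control
profile repeats the procedure on the most confident negatives.

## Statistics

AUC is the midrank Mann–Whitney statistic. The DeLong test computes
per-record placement values (structural components) for both score
vectors, estimates the covariance of the paired AUCs with sample
covariances scaled by class sizes, and refers `ΔAUC/√var` to the standard
normal, two-sided; ties are handled by midranks throughout, and the
degenerate zero-variance case returns p = 1 when ΔAUC = 0 and p = 0 with
a warning otherwise. Benjamini–Hochberg adjustment and the Pearson test
delegate to statsmodels and scipy respectively; tests verify them against
hand-stepped and arbitrary-precision evaluations, the AUC against
exhaustive pair enumeration, and the DeLong variance against a hand-worked
3 + 3 example. A Monte-Carlo null (two noisy readouts of one latent
score, 200 per class, 2000 replicates) confirms type-I error at the
nominal 5% level.

## Orchestration and scale

`run_matrix` mirrors the study design — one pretraining per tokenizer on
pooled positive training data, one fine-tune per organism × negative
strategy, evaluation on the held-out test set, all jobs cached by config
hash for idempotent resume. The test suite and the acceptance script run
the whole pipeline at reduced problem sizes (hundreds of promoters,
1–2-layer encoders, vocabularies of tens to a few thousand tokens),
chosen so the full suite completes in minutes on one CPU while every
qualitative property — planted-motif recovery at +90 within ±12 nt in the
majority of seeded runs, absent in the negative control; leakage-free
splits verified exhaustively; conservation constraints checked
byte-by-byte — is exercised end to end.

## Design shape

The modeling layer follows the model/results idiom (`MaskedLanguageModel`
and `PromoterClassifier` build from data and configuration; `fit()`
returns results objects carrying state, traces, predictions and
`summary()`); the surrounding stages are data transformations and keep a
functional surface.

## Known limitations

* Hamming identity under-clusters relative to alignment-based tools for
  sequences related by indels; real-data use should import `.clstr`.
* The numpy encoder is single-threaded and desk-scale; the configuration
  scales up, the wall-clock does not.
* The sampling Shapley estimator is exact only in expectation; tests pin
  it down on stub models with known answers.
* Whether the original WPC threshold acted on pair counts or scores is
  not determinable from the source; both stop modes are provided.
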