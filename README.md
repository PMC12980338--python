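# promtok

A desk-scale, fully reproducible pipeline for building and comparing
**promoter classifiers** from DNA sequence. The package re-creates, on
synthetic data, the complete comparative framework used to study how design
choices — negative-set construction, redundancy-aware data splitting, DNA
tokenization scheme, and pretraining curriculum — shape the performance and
the *positional attention* of transformer promoter models.

## The problem

Promoters are the regulatory regions around transcription start sites
(TSSs). Classifiers are trained on 601-nt windows spanning −300..+300
around experimentally verified TSSs (the positive class), but everything
else about the experiment is a design choice with scientific consequences:

* **Negatives.** Two standard recipes are implemented exactly:
  *positive-promoter-shuffled* (each positive is cut into 25 fixed 24-nt
  segments; 8 are drawn at random and permuted in place, 17 left untouched,
  so nucleotide composition is conserved and ~68% of the sequence is
  byte-identical) and *random-non-promoter-fragments* (windows centered on
  random TSSs from the same chromosome, ≥ 600 nt from every other TSS).
  With a TATA-box prevalence of *p* in the positives, shuffling retains an
  expected *p*·17/25 in the negatives (12.9% → 8.8%), a built-in class
  signal the framework makes explicit and testable.
* **Splitting.** Sequences are clustered at 80% ungapped identity
  (CD-HIT-style `.clstr` files can be imported) and whole clusters are
  accumulated smallest-first into test (20%), then validation (15%), then
  train — so no near-duplicate pair ever straddles partitions, and
  negatives always follow their paired positive.
* **Tokenization.** Non-overlapping and overlapping 6-mers, byte-pair
  encoding (merge the most frequent adjacent pair), a WordPiece-style
  scheme (merge the pair maximizing `count(ab)/(count(a)·count(b))`), and a
  character baseline — all with per-token nucleotide spans so attribution
  can be mapped back onto positions.
* **Models.** A small numpy transformer encoder (masked-LM pretraining on
  positives only, optionally under an *evolutionary-informed* curriculum
  that restricts late epochs to the phylogenetically nearest species, then
  binary fine-tuning).
* **Explanation.** Occlusion or Monte-Carlo Shapley token attribution on
  the 100 most confident test predictions, broadcast to nucleotides and
  averaged into a length-601 positional profile (window index *i* ↔ TSS
  offset *i* − 300; index 390 ↔ +90).
* **Statistics.** Mann–Whitney AUC, the DeLong test for correlated ROC
  curves (hand-implemented structural components, midrank ties),
  Benjamini–Hochberg FDR, and the Pearson distance–performance test.

A first-class synthetic-data generator emulates multi-organism promoter
corpora — planted TATA-boxes (12.9% by default), a downstream element at
+90, phylogeny-correlated background composition, chromosome-scale
background, near-duplicate families, and rare `N` bases — so every stage
is testable end to end without downloads.

## Worked example

```python
import promtok as pt
from promtok.modeling import EncoderConfig, TrainConfig, tokenize_windows
from promtok.attribution import (peak_report, positional_profile,
                                 select_top_confident, token_attribution)

cfg = pt.SimConfig(n_organisms=1, promoters_per_organism=220,
                   chromosome_length=600_000, family_count=0, seed=0)
genomes = pt.synthesize_genome_set(cfg, pt.generate_phylogeny(preset="epd8"))
positives = pt.positive_windows(genomes)
negatives = pt.build_negative_set(positives, genomes, "fragment", seed=1)

clusters = pt.greedy_cluster({w.id: w.sequence for w in positives})
split = pt.propagate_pairs(pt.accumulate_split(clusters), negatives)
pool = positives + negatives
tr, va, te = (
    [w for w in pool if split.partition[w.id] == part]
    for part in ("train", "validation", "test")
)

vocab = pt.build_kmer_vocab([w.sequence for w in positives], 6)
clf = pt.PromoterClassifier.from_windows(
    tr, va, "kmer_nonoverlap", vocab,
    encoder_config=EncoderConfig(layers=1, hidden=32, heads=2, max_tokens=128),
).fit(TrainConfig(epochs=5, seed=0, learning_rate=2e-3))

te_seqs = tokenize_windows(te, "kmer_nonoverlap", vocab)
preds = clf.predict(te_seqs)
scores, labels, _ = preds.arrays()
print(f"test AUC: {pt.auc(scores, labels):.3f}")

by_id = {t.window_id: t for t in te_seqs}
top = select_top_confident(preds, "positive", 30)
profile = positional_profile([token_attribution(clf, by_id[i]) for i in top])
print(peak_report(profile, top_k=1)[0])
```

Output:

```
split: 286 train / 66 validation / 88 test
test AUC: 0.987
attribution peak at window index 390 (TSS offset +90), height 0.242
```

The classifier separates promoters from fragment negatives (AUC 0.987),
and the positional attribution profile peaks exactly at the planted
downstream element: window index 390, i.e. +90 nt downstream of the TSS.
The negative-control profile (most-confident negatives) shows no
comparable peak — see `tests/test_acceptance.py`.

A `promtok` command-line interface wraps the same stages
(`simulate`, `make-negatives`, `split`, `train-tokenizer`, `pretrain`,
`finetune`, `matrix`); run `promtok --help`.

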