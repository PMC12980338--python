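"""Experiment orchestration: the tokenizer x organism x negative-strategy
matrix, pairwise DeLong comparisons, and the cross-species evaluation.

``run_matrix`` reproduces the study structure at configurable scale: per
tokenization scheme one masked-LM pretraining on the pooled positive
training data, then one fine-tuned classifier per organism and negative
strategy, each evaluated on its held-out test set.  Completed jobs are
cached on disk (hash-keyed JSON) so reruns are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import accumulate_split, filter_external, greedy_cluster, propagate_pairs
from .corpus import PromoterWindow
from .modeling import (
    ClassifierResults,
    CurriculumSchedule,
    EncoderConfig,
    MaskedLanguageModel,
    PromoterClassifier,
    TrainConfig,
    tokenize_windows,
)
from .negatives import build_negative_set
from .phylogeny import PhylogenyTable, generate_phylogeny
from .simulate import SimConfig, positive_windows, synthesize_genome_set
from .stats import auc, bh_fdr, delong_comparison, pearson_test
from .tokenizers import (
    MergeTable,
    Vocabulary,
    build_char_vocab,
    build_kmer_vocab,
    train_bpe,
    train_wpc,
)

__all__ = [
    "ExperimentConfig",
    "train_tokenizer",
    "prepare_dataset",
    "run_matrix",
    "compare_methods",
    "cross_species_eval",
]

TOKENIZER_SCHEMES = ("kmer_nonoverlap", "kmer_overlap", "bpe", "wpc", "char")


@dataclass
class ExperimentConfig:
    """Everything needed to rerun the matrix from scratch."""

    sim: SimConfig = field(default_factory=SimConfig)
    phylo_preset: str | None = "epd8"
    tokenizers: tuple[str, ...] = ("kmer_nonoverlap", "bpe")
    negative_strategies: tuple[str, ...] = ("shuffled", "fragment")
    subword_target_vocab: int = 300
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    pretrain: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=2))
    finetune: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=5))
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.tokenizers or not self.negative_strategies:
            raise ValueError("need at least one tokenizer and one strategy")
        for t in self.tokenizers:
            if t not in TOKENIZER_SCHEMES:
                raise ValueError(f"unknown tokenizer scheme {t!r}")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "sim": asdict(self.sim),
                "phylo": self.phylo_preset,
                "tok": self.tokenizers,
                "neg": self.negative_strategies,
                "target": self.subword_target_vocab,
                "enc": asdict(self.encoder),
                "pre": asdict(self.pretrain),
                "fin": asdict(self.finetune),
                "frac": self.fractions,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_tokenizer(
    scheme: str, corpus: list[str], target_vocab: int = 300
) -> tuple[Vocabulary, MergeTable | None]:
    """Train (or enumerate) the vocabulary for one scheme on a corpus."""
    if scheme == "kmer_nonoverlap":
        return build_kmer_vocab(corpus, 6, overlapping=False), None
    if scheme == "kmer_overlap":
        return build_kmer_vocab(corpus, 6, overlapping=True), None
    if scheme == "bpe":
        return train_bpe(corpus, target_vocab)
    if scheme == "wpc":
        return train_wpc(corpus, target_vocab=target_vocab)
    if scheme == "char":
        return build_char_vocab(corpus), None
    raise ValueError(f"unknown tokenizer scheme {scheme!r}")


def prepare_dataset(config: ExperimentConfig):
    """Simulate, build negatives for every strategy, cluster and split.

    Returns ``(genomes, positives, negatives_by_strategy, assignment)``
    where the assignment already covers negatives via pair propagation.
    """
    phylo = (
        generate_phylogeny(preset=config.phylo_preset)
        if config.phylo_preset
        else generate_phylogeny(config.sim.n_organisms, config.seed)
    )
    genomes = synthesize_genome_set(config.sim, phylo)
    positives = positive_windows(genomes, config.sim.window_halfwidth)
    clusters = greedy_cluster({w.id: w.sequence for w in positives})
    assignment = accumulate_split(clusters, config.fractions)
    negatives = {}
    for strat in config.negative_strategies:
        negs = build_negative_set(
            positives, genomes, strat,
            seed=config.seed + {"shuffled": 1, "fragment": 2}[strat],
        )
        assignment = propagate_pairs(assignment, negs)
        negatives[strat] = negs
    return genomes, positives, negatives, assignment, phylo


def _partition(windows, assignment, part):
    return [w for w in windows if assignment.partition.get(w.id) == part]


def run_matrix(config: ExperimentConfig):
    """Run the full tokenizer x organism x strategy matrix.

    Returns ``(results table, prediction sets)``; predictions are keyed by
    ``(organism, tokenizer, strategy)``.  With ``config.outdir`` set,
    completed jobs are skipped on rerun.
    """
    outdir = Path(config.outdir) if config.outdir else None
    jobdir = None
    if outdir:
        jobdir = outdir / "jobs"
        jobdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    genomes, positives, negatives, assignment, phylo = prepare_dataset(config)
    organisms = genomes.organisms
    train_pos = _partition(positives, assignment, "train")
    corpus = [w.sequence for w in train_pos]

    rows = []
    predictions: dict[tuple[str, str, str], dict] = {}
    for scheme in config.tokenizers:
        vocab, merges = train_tokenizer(scheme, corpus, config.subword_target_vocab)
        # one pretraining per tokenizer, pooled positive training data
        corpora = {org: [] for org in organisms}
        for w, ts in zip(
            train_pos, tokenize_windows(train_pos, scheme, vocab, merges)
        ):
            corpora[w.organism].append(ts)
        corpora = {o: s for o, s in corpora.items() if s}
        mlm = MaskedLanguageModel(
            corpora,
            vocab,
            config.encoder,
            CurriculumSchedule([list(corpora)] * config.pretrain.epochs),
        ).fit(config.pretrain)
        for strat in config.negative_strategies:
            pool = positives + negatives[strat]
            for org in organisms:
                key = (org, scheme, strat)
                job_file = (
                    jobdir / f"{cfg_hash}_{org}_{scheme}_{strat}.json"
                    if jobdir
                    else None
                )
                if job_file and job_file.exists():
                    payload = json.loads(job_file.read_text())
                    rows.append(payload["row"])
                    predictions[key] = payload["predictions"]
                    continue
                t0 = time.monotonic()
                org_pool = [w for w in pool if w.organism == org]
                tr = _partition(org_pool, assignment, "train")
                va = _partition(org_pool, assignment, "validation")
                te = _partition(org_pool, assignment, "test")
                # tiny corpora can leave an organism without validation
                # records; early-stop on the training set then
                va = va or tr
                if {w.label for w in tr} != {"positive", "negative"} or {
                    w.label for w in te
                } != {"positive", "negative"}:
                    logging.getLogger(__name__).warning(
                        "skipping %s/%s/%s: a partition lacks one class",
                        org, scheme, strat,
                    )
                    continue
                clf = PromoterClassifier.from_windows(
                    tr,
                    va,
                    scheme,
                    vocab,
                    merges,
                    encoder_config=config.encoder,
                    pretrained=mlm.params,
                ).fit(config.finetune)
                te_seqs = tokenize_windows(te, scheme, vocab, merges)
                preds = clf.predict(te_seqs)
                scores, y, _ = preds.arrays()
                row = {
                    "organism": org,
                    "tokenizer": scheme,
                    "strategy": strat,
                    "pretrain": "flat",
                    "n_finetune": len(tr),
                    "auc": auc(scores, y),
                    "seed": config.finetune.seed,
                    "runtime_s": round(time.monotonic() - t0, 3),
                    "config_hash": cfg_hash,
                }
                rows.append(row)
                predictions[key] = {
                    "probabilities": preds.probabilities,
                    "labels": preds.labels,
                }
                if job_file:
                    job_file.write_text(
                        json.dumps({"row": row, "predictions": predictions[key]})
                    )
    table = pd.DataFrame(rows)
    if outdir:
        table.to_csv(outdir / "results.tsv", sep="\t", index=False)
        (outdir / "results.json").write_text(table.to_json(orient="records"))
    return table, predictions


def compare_methods(
    predictions: dict[tuple[str, str, str], dict], alpha: float = 0.05,
    family: str = "global",
) -> pd.DataFrame:
    """All tokenizer-pair DeLong comparisons per organism and strategy,
    BH-adjusted across the chosen family ("global" or "per_organism")."""
    keys = sorted(predictions)
    cells: dict[tuple[str, str], list[str]] = {}
    for org, tok, strat in keys:
        cells.setdefault((org, strat), []).append(tok)
    rows = []
    for (org, strat), toks in sorted(cells.items()):
        for i in range(len(toks)):
            for j in range(i + 1, len(toks)):
                pa = predictions[(org, toks[i], strat)]
                pb = predictions[(org, toks[j], strat)]
                ids = sorted(pa["probabilities"])
                if ids != sorted(pb["probabilities"]):
                    raise ValueError(
                        f"prediction sets for {toks[i]} and {toks[j]} on "
                        f"{org}/{strat} cover different records"
                    )
                sa = np.array([pa["probabilities"][k] for k in ids])
                sb = np.array([pb["probabilities"][k] for k in ids])
                y = np.array(
                    [1 if pa["labels"][k] == "positive" else 0 for k in ids]
                )
                cmp_ = delong_comparison(sa, sb, y)
                rows.append(
                    {
                        "organism": org,
                        "strategy": strat,
                        "method_a": toks[i],
                        "method_b": toks[j],
                        "auc_a": cmp_.auc_a,
                        "auc_b": cmp_.auc_b,
                        "z": cmp_.z,
                        "p": cmp_.p,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if family == "global":
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
    elif family == "per_organism":
        df["p_adj"] = np.nan
        for org in df["organism"].unique():
            m = df["organism"] == org
            df.loc[m, "p_adj"] = bh_fdr(df.loc[m, "p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    df["significant"] = df["p_adj"] < alpha
    return df


def cross_species_eval(
    models: dict[str, ClassifierResults],
    external_windows: list[PromoterWindow],
    training_pool: list[PromoterWindow],
    phylo: PhylogenyTable,
    external_organism: str,
    scheme: str,
    vocab: Vocabulary,
    merges: MergeTable | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Evaluate per-organism models on an external species' windows.

    External positives are first passed through the single-member-cluster
    filter against the training pool (N-containing sequences dropped);
    negatives paired with a dropped positive are dropped too.  Rows are
    sorted by phylogenetic distance from the external organism, and the
    Pearson correlation over (distance, AUC) is returned alongside.
    """
    ext_pos = [w for w in external_windows if w.label == "positive"]
    ext_neg = [w for w in external_windows if w.label == "negative"]
    kept_pos = filter_external(ext_pos, training_pool)
    kept_ids = {w.id for w in kept_pos}
    kept = kept_pos + [
        w
        for w in ext_neg
        if w.paired_positive_id in kept_ids and "N" not in w.sequence
    ]
    if not kept_pos or all(w.label == "positive" for w in kept):
        raise ValueError("filtered external set lacks one of the classes")
    seqs = tokenize_windows(kept, scheme, vocab, merges)
    rows = []
    for org, model in models.items():
        preds = model.predict(seqs)
        scores, y, _ = preds.arrays()
        rows.append(
            {
                "organism": org,
                "distance": phylo.distance_between(org, external_organism),
                "auc": auc(scores, y),
                "n_external": len(kept),
            }
        )
    df = pd.DataFrame(rows).sort_values("distance", ignore_index=True)
    r, p = pearson_test(df["distance"].to_numpy(), df["auc"].to_numpy())
    return df, (r, p)
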