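"""Masked-LM pretraining (flat vs evolutionary-informed curricula) and
binary promoter classification.

The layer follows the model/results idiom: :class:`MaskedLanguageModel`
and :class:`PromoterClassifier` are built from data and configuration, and
their ``fit()`` returns a results object carrying the trained state, loss
traces, diagnostics and a ``summary()`` table.

Pretraining consumes *positive* windows only (a hard contract) and follows
a per-epoch curriculum: the flat schedule uses every organism each epoch,
the evolutionary-informed schedule uses every organism for the first half
of pretraining and only the target organism's nearest phylogenetic
neighbours afterwards — so the flat model sees roughly twice the
observations in the second half.  An epoch is one pass over the union of
that epoch's scheduled organisms' sequences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, EncoderConfig, TransformerEncoder, init_params
from .phylogeny import PhylogenyTable, nearest_species
from .tokenizers import SPECIALS, MergeTable, TokenizedSequence, Vocabulary, encode

__all__ = [
    "TrainConfig",
    "CurriculumSchedule",
    "make_schedule",
    "tokenize_windows",
    "MaskedLanguageModel",
    "MLMResults",
    "PromoterClassifier",
    "ClassifierResults",
    "PredictionSet",
    "pretrain_mlm",
    "finetune_classifier",
    "predict",
    "ablation_curve",
    "nearest_species",
    "EncoderConfig",
]


@dataclass
class TrainConfig:
    """Optimization knobs shared by pretraining and fine-tuning."""

    batch_size: int = 8
    learning_rate: float = 1e-3
    epochs: int = 10
    mlm_mask_rate: float = 0.15
    seed: int = 0
    patience: int = 3

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.mlm_mask_rate < 1.0:
            raise ValueError("mlm_mask_rate must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class CurriculumSchedule:
    """Organism subsets driving each pretraining epoch."""

    epoch_organisms: list[list[str]]

    def __post_init__(self) -> None:
        if not self.epoch_organisms:
            raise ValueError("schedule must cover at least one epoch")
        for i, orgs in enumerate(self.epoch_organisms):
            if not orgs:
                raise ValueError(f"epoch {i + 1} has an empty organism subset")

    @property
    def epochs(self) -> int:
        return len(self.epoch_organisms)


def make_schedule(
    strategy: str,
    organisms: list[str],
    phylo: PhylogenyTable | None = None,
    target: str | None = None,
    epochs: int = 10,
    switch_epoch: int = 5,
    m: int = 4,
) -> CurriculumSchedule:
    """Build the flat or evolutionary-informed curriculum.

    ``flat``: every organism in every epoch.  ``evolutionary``: every
    organism for epochs ``1..switch_epoch``, then only the ``m`` organisms
    closest to ``target`` (target included).
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if switch_epoch > epochs:
        raise ValueError("switch_epoch cannot exceed epochs")
    if strategy == "flat":
        return CurriculumSchedule([list(organisms)] * epochs)
    if strategy != "evolutionary":
        raise ValueError(f"unknown strategy {strategy!r}")
    if phylo is None or target is None:
        raise ValueError("evolutionary schedule needs a phylogeny and target")
    near = nearest_species(phylo, target, m)
    missing = set(near) - set(organisms)
    if missing:
        raise ValueError(f"nearest species {sorted(missing)} not in corpus")
    return CurriculumSchedule(
        [list(organisms)] * switch_epoch + [list(near)] * (epochs - switch_epoch)
    )


def tokenize_windows(
    windows,
    scheme: str,
    vocab: Vocabulary,
    merges: MergeTable | None = None,
) -> list[TokenizedSequence]:
    """Encode promoter windows, carrying label and organism provenance."""
    out = []
    for w in windows:
        ts = encode(w.sequence, scheme, vocab, merges, window_id=w.id)
        ts.label = w.label
        ts.organism = w.organism
        out.append(ts)
    return out


# ---------------------------------------------------------------------------
# batching


def _pad_batch(seqs: list[TokenizedSequence], vocab: Vocabulary):
    """Prepend [CLS], pad to the longest sequence; True marks real tokens."""
    L = max(len(s) for s in seqs) + 1
    B = len(seqs)
    ids = np.full((B, L), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, 0] = vocab.cls_id
        ids[i, 1 : 1 + len(s)] = s.ids
        mask[i, : 1 + len(s)] = True
    return ids, mask


def _apply_mlm_mask(ids, mask, vocab, rate, rng):
    """BERT-style corruption: of the selected content positions, 80% become
    [MASK], 10% a random content token, 10% stay."""
    content = mask & (ids >= len(SPECIALS))
    sel = content & (rng.random(ids.shape) < rate)
    b_idx, p_idx = np.nonzero(sel)
    target_ids = ids[b_idx, p_idx].copy()
    corrupted = ids.copy()
    u = rng.random(len(b_idx))
    n_content = len(vocab) - len(SPECIALS)
    rand_tok = rng.integers(0, n_content, len(b_idx)) + len(SPECIALS)
    for j in range(len(b_idx)):
        if u[j] < 0.8:
            corrupted[b_idx[j], p_idx[j]] = vocab.mask_id
        elif u[j] < 0.9:
            corrupted[b_idx[j], p_idx[j]] = rand_tok[j]
    return corrupted, np.stack([b_idx, p_idx], axis=1), target_ids


# ---------------------------------------------------------------------------
# masked language model


class MaskedLanguageModel:
    """MLM pretraining over per-organism positive corpora.

    Parameters
    ----------
    corpora : dict of organism -> list of TokenizedSequence
        Pretraining material; every sequence must be labeled ``positive``.
    vocab : Vocabulary
    encoder_config : EncoderConfig, optional
    schedule : CurriculumSchedule, optional
        Defaults to a flat schedule over all organisms for
        ``TrainConfig.epochs`` epochs.
    """

    def __init__(
        self,
        corpora: dict[str, list[TokenizedSequence]],
        vocab: Vocabulary,
        encoder_config: EncoderConfig | None = None,
        schedule: CurriculumSchedule | None = None,
    ):
        for org, seqs in corpora.items():
            for s in seqs:
                if s.label != "positive":
                    raise ValueError(
                        f"pretraining corpus for {org} contains a "
                        f"non-positive window {s.window_id!r} "
                        f"(label={s.label!r})"
                    )
        self.corpora = corpora
        self.vocab = vocab
        self.encoder_config = encoder_config or EncoderConfig()
        self.schedule = schedule

    def fit(self, train_config: TrainConfig | None = None) -> "MLMResults":
        cfg = train_config or TrainConfig()
        schedule = self.schedule or CurriculumSchedule(
            [list(self.corpora)] * cfg.epochs
        )
        missing = {o for ep in schedule.epoch_organisms for o in ep} - set(
            self.corpora
        )
        if missing:
            raise ValueError(f"schedule names organisms without corpora: {missing}")
        rng = np.random.default_rng(cfg.seed)
        enc = TransformerEncoder(self.encoder_config, len(self.vocab))
        params = init_params(self.encoder_config, len(self.vocab), rng)
        opt = Adam(params, lr=cfg.learning_rate)
        epoch_losses: list[float] = []
        batch_log: list[dict] = []
        masked_fraction: list[float] = []
        for ep, orgs in enumerate(schedule.epoch_organisms):
            pool: list[TokenizedSequence] = []
            for org in orgs:
                pool.extend(self.corpora[org])
            order = rng.permutation(len(pool))
            losses = []
            n_masked = n_content = 0
            for start in range(0, len(pool), cfg.batch_size):
                batch = [pool[j] for j in order[start : start + cfg.batch_size]]
                ids, mask = _pad_batch(batch, self.vocab)
                corrupted, tpos, tids = _apply_mlm_mask(
                    ids, mask, self.vocab, cfg.mlm_mask_rate, rng
                )
                if len(tids) == 0:
                    continue
                hidden, cache = enc.forward(params, corrupted, mask, train=True,
                                            drop_rng=rng)
                loss, dhidden, head_grads = enc.mlm_loss(
                    params, hidden, cache, tpos, tids
                )
                grads = enc.backward(params, cache, dhidden)
                for k, g in head_grads.items():
                    grads[k] += g
                opt.step(params, grads)
                losses.append(loss)
                n_masked += len(tids)
                n_content += int((mask & (ids >= len(SPECIALS))).sum())
                batch_log.append(
                    {"epoch": ep + 1, "organisms": sorted({b.organism for b in batch})}
                )
            epoch_losses.append(float(np.mean(losses)) if losses else float("nan"))
            masked_fraction.append(n_masked / n_content if n_content else 0.0)
        return MLMResults(
            params=params,
            encoder_config=self.encoder_config,
            vocab=self.vocab,
            schedule=schedule,
            train_config=cfg,
            epoch_losses=epoch_losses,
            batch_log=batch_log,
            masked_fraction=masked_fraction,
        )


@dataclass
class MLMResults:
    params: dict
    encoder_config: EncoderConfig
    vocab: Vocabulary
    schedule: CurriculumSchedule
    train_config: TrainConfig
    epoch_losses: list[float]
    batch_log: list[dict]
    masked_fraction: list[float]

    def summary(self) -> str:
        lines = [
            "Masked language model pretraining",
            f"  vocabulary size: {len(self.vocab)} ({self.vocab.scheme})",
            f"  encoder: {self.encoder_config.layers} layers, "
            f"{self.encoder_config.hidden} hidden, "
            f"{self.encoder_config.heads} heads",
            f"  epochs: {len(self.epoch_losses)}",
        ]
        for i, (loss, orgs) in enumerate(
            zip(self.epoch_losses, self.schedule.epoch_organisms)
        ):
            lines.append(
                f"  epoch {i + 1:2d}: loss {loss:.4f}  ({len(orgs)} organisms)"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class PredictionSet:
    """Per-record promoter probabilities plus true labels."""

    probabilities: dict[str, float]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for wid, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0 or not np.isfinite(p):
                raise ValueError(f"probability for {wid} outside [0, 1]: {p}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        ids = sorted(self.probabilities)
        scores = np.array([self.probabilities[i] for i in ids])
        y = np.array([1 if self.labels[i] == "positive" else 0 for i in ids])
        return scores, y, ids


class PromoterClassifier:
    """Binary promoter/non-promoter classifier over tokenized windows.

    Built from labeled train and validation sets; ``pretrained`` warm-starts
    the encoder from a :class:`MLMResults` state (omit for the
    no-pretraining baseline).  ``fit()`` early-stops on validation loss and
    restores the best epoch's weights.
    """

    def __init__(
        self,
        train: list[TokenizedSequence],
        validation: list[TokenizedSequence],
        vocab: Vocabulary,
        encoder_config: EncoderConfig | None = None,
        pretrained: dict | None = None,
    ):
        labels = {s.label for s in train}
        if labels != {"positive", "negative"}:
            raise ValueError(
                f"training data must contain both classes, got {sorted(labels)}"
            )
        self.train_set = train
        self.val_set = validation
        self.vocab = vocab
        self.encoder_config = encoder_config or EncoderConfig()
        self.pretrained = pretrained

    @classmethod
    def from_windows(
        cls,
        train_windows,
        val_windows,
        scheme: str,
        vocab: Vocabulary,
        merges: MergeTable | None = None,
        **kwargs,
    ) -> "PromoterClassifier":
        return cls(
            tokenize_windows(train_windows, scheme, vocab, merges),
            tokenize_windows(val_windows, scheme, vocab, merges),
            vocab,
            **kwargs,
        )

    def _eval_loss(self, enc, params, seqs, batch_size) -> float:
        losses, weights = [], []
        for start in range(0, len(seqs), batch_size):
            batch = seqs[start : start + batch_size]
            ids, mask = _pad_batch(batch, self.vocab)
            hidden, _ = enc.forward(params, ids, mask)
            probs = enc.cls_forward(params, hidden)
            y = np.array([1.0 if b.label == "positive" else 0.0 for b in batch])
            losses.append(
                float(
                    -(
                        y * np.log(probs + 1e-12)
                        + (1 - y) * np.log(1 - probs + 1e-12)
                    ).mean()
                )
            )
            weights.append(len(batch))
        return float(np.average(losses, weights=weights))

    def fit(self, train_config: TrainConfig | None = None) -> "ClassifierResults":
        cfg = train_config or TrainConfig(epochs=20)
        rng = np.random.default_rng(cfg.seed)
        enc = TransformerEncoder(self.encoder_config, len(self.vocab))
        params = init_params(self.encoder_config, len(self.vocab), rng)
        if self.pretrained is not None:
            for k, v in self.pretrained.items():
                if params[k].shape != v.shape:
                    raise ValueError(
                        f"pretrained state mismatch at {k}: "
                        f"{v.shape} vs {params[k].shape}"
                    )
                params[k] = v.copy()
        opt = Adam(params, lr=cfg.learning_rate)
        train_curve, val_curve = [], []
        best_val = np.inf
        best_params = None
        best_epoch = -1
        bad = 0
        for ep in range(cfg.epochs):
            order = rng.permutation(len(self.train_set))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = [
                    self.train_set[j] for j in order[start : start + cfg.batch_size]
                ]
                ids, mask = _pad_batch(batch, self.vocab)
                y = np.array([1.0 if b.label == "positive" else 0.0 for b in batch])
                hidden, cache = enc.forward(params, ids, mask, train=True,
                                            drop_rng=rng)
                loss, dhidden, head_grads = enc.cls_loss(params, hidden, y)
                grads = enc.backward(params, cache, dhidden)
                for k, g in head_grads.items():
                    grads[k] += g
                opt.step(params, grads)
                losses.append(loss)
            train_curve.append(float(np.mean(losses)))
            vloss = self._eval_loss(enc, params, self.val_set, cfg.batch_size)
            val_curve.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = copy.deepcopy(params)
                best_epoch = ep
                bad = 0
            else:
                bad += 1
                if bad > cfg.patience:
                    break
        return ClassifierResults(
            params=best_params if best_params is not None else params,
            encoder_config=self.encoder_config,
            vocab=self.vocab,
            train_config=cfg,
            train_curve=train_curve,
            val_curve=val_curve,
            best_epoch=best_epoch,
            pretrained=self.pretrained is not None,
        )


@dataclass
class ClassifierResults:
    params: dict
    encoder_config: EncoderConfig
    vocab: Vocabulary
    train_config: TrainConfig
    train_curve: list[float]
    val_curve: list[float]
    best_epoch: int
    pretrained: bool

    def _encoder(self) -> TransformerEncoder:
        return TransformerEncoder(self.encoder_config, len(self.vocab))

    def predict_proba(self, seqs: list[TokenizedSequence], batch_size: int = 8):
        enc = self._encoder()
        out = np.empty(len(seqs))
        for start in range(0, len(seqs), batch_size):
            batch = seqs[start : start + batch_size]
            for s in batch:
                if len(s.ids) and int(s.ids.max()) >= len(self.vocab):
                    raise ValueError(
                        f"window {s.window_id!r} tokenized with a larger "
                        "vocabulary than the classifier's"
                    )
            ids, mask = _pad_batch(batch, self.vocab)
            hidden, _ = enc.forward(self.params, ids, mask)
            out[start : start + len(batch)] = enc.cls_forward(self.params, hidden)
        return out

    def predict(
        self, seqs: list[TokenizedSequence], batch_size: int = 8
    ) -> PredictionSet:
        probs = self.predict_proba(seqs, batch_size)
        return PredictionSet(
            probabilities={s.window_id: float(p) for s, p in zip(seqs, probs)},
            labels={s.window_id: (s.label or "unknown") for s in seqs},
        )

    def summary(self) -> str:
        lines = [
            "Promoter classifier",
            f"  vocabulary size: {len(self.vocab)} ({self.vocab.scheme})",
            f"  pretrained encoder: {'yes' if self.pretrained else 'no'}",
            f"  epochs run: {len(self.train_curve)} "
            f"(best validation at epoch {self.best_epoch + 1})",
            f"  final train loss: {self.train_curve[-1]:.4f}",
            f"  best validation loss: {min(self.val_curve):.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers and the fine-tuning-size ablation


def pretrain_mlm(
    encoder_config: EncoderConfig,
    corpora: dict[str, list[TokenizedSequence]],
    schedule: CurriculumSchedule,
    train_config: TrainConfig,
    vocab: Vocabulary,
) -> MLMResults:
    return MaskedLanguageModel(corpora, vocab, encoder_config, schedule).fit(
        train_config
    )


def finetune_classifier(
    pretrained: dict | None,
    train: list[TokenizedSequence],
    validation: list[TokenizedSequence],
    vocab: Vocabulary,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
) -> ClassifierResults:
    return PromoterClassifier(
        train, validation, vocab, encoder_config, pretrained
    ).fit(train_config)


def predict(
    results: ClassifierResults, seqs: list[TokenizedSequence], batch_size: int = 8
) -> PredictionSet:
    return results.predict(seqs, batch_size)


def ablation_curve(
    pretrained_states: dict[str, dict],
    pool: list[TokenizedSequence],
    sizes: list[int],
    test: list[TokenizedSequence],
    vocab: Vocabulary,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    replicates: int = 5,
    val_fraction: float = 0.2,
) -> pd.DataFrame:
    """Fine-tuning-set-size ablation.

    For each pretraining strategy, replicate and size ``n``: fine-tune from
    the pretrained state on a class-balanced subsample of ``pool`` (n/2
    positives, n/2 negatives; subsamples nested so each size extends the
    previous one), then evaluate AUC on the fixed ``test`` set.  A
    ``val_fraction`` tail of each subsample serves as the early-stopping
    validation set.  Replicates reshuffle the pool with distinct seeds.
    """
    from .stats import auc

    base_cfg = train_config or TrainConfig(epochs=10)
    pos = [s for s in pool if s.label == "positive"]
    neg = [s for s in pool if s.label == "negative"]
    max_n = max(sizes)
    if any(n % 2 for n in sizes):
        raise ValueError("sizes must be even (balanced classes)")
    if len(pos) < max_n // 2 or len(neg) < max_n // 2:
        raise ValueError(
            f"pool too small for size {max_n}: {len(pos)} positives, "
            f"{len(neg)} negatives"
        )
    rows = []
    for strategy, state in pretrained_states.items():
        for rep in range(replicates):
            rng = np.random.default_rng(base_cfg.seed + 1000 * (rep + 1))
            pos_order = [pos[i] for i in rng.permutation(len(pos))]
            neg_order = [neg[i] for i in rng.permutation(len(neg))]
            for n in sorted(sizes):
                half = n // 2
                n_val = max(2, int(n * val_fraction))
                # interleave classes so the validation tail stays mixed
                inter = [s for pair in zip(pos_order[:half], neg_order[:half])
                         for s in pair]
                train_s, val_s = inter[:-n_val], inter[-n_val:]
                cfg = TrainConfig(
                    batch_size=base_cfg.batch_size,
                    learning_rate=base_cfg.learning_rate,
                    epochs=base_cfg.epochs,
                    mlm_mask_rate=base_cfg.mlm_mask_rate,
                    seed=base_cfg.seed + 1000 * (rep + 1),
                    patience=base_cfg.patience,
                )
                res = finetune_classifier(
                    state, train_s, val_s, vocab, encoder_config, cfg
                )
                preds = res.predict(test)
                scores, y, _ = preds.arrays()
                rows.append(
                    {
                        "strategy": strategy,
                        "n": n,
                        "replicate": rep,
                        "auc": auc(scores, y),
                    }
                )
    return pd.DataFrame(rows)
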