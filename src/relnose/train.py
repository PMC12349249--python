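"""Episodic few-shot training and evaluation.

One training step = one N-way K-shot episode sampled from the meta-training
bundle, channel-shuffle augmentation (a single sensor permutation shared by
the episode's support and query samples), a model-specific loss, and one
Adam update:

* relation / siamese heads regress their (0, 1) similarity scores onto the
  0/1 relation targets with a summed squared-error loss;
* the prototypical head minimizes the negative log-likelihood of the true
  class under its distance softmax.

Every ``eval_every`` epochs the model is tested on the meta-testing bundle
with ``test_episodes`` freshly sampled episodes; predictions are pooled
over those episodes into one accuracy and one macro-F1 per test.  The
records collected between two epochs of interest (e.g. 700–1000) aggregate
into means and t-interval half-widths.

Everything — episode draws, augmentation, dropout, parameter init — is
driven by generators derived from a single seed, so a run is exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Parameter, Tensor, sum_, use_dtype
from .episodes import Episode, EpisodeSpec, relation_targets, sample_episode
from .metrics import RunStatistics, accuracy, confusion, macro_f1, run_statistics
from .nets import build_model
from .signal_io import DatasetBundle, channel_shuffle

logger = logging.getLogger(__name__)

DEFAULT_LEARNING_RATES = {"relation": 1e-4, "siamese": 1e-4, "proto": 1e-5}


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    model: str = "relation"
    learning_rate: float | None = None   # per-model default if None
    epochs: int = 1001
    eval_every: int = 20
    test_episodes: int = 50
    seed: int = 512
    spec: EpisodeSpec = field(default_factory=EpisodeSpec)
    shuffle_channels: bool = True
    loss_reduction: str = "sum"          # "sum" | "mean"
    pooled_metrics: bool = True
    dtype: str = "float32"               # compute precision of the run

    def __post_init__(self) -> None:
        if self.learning_rate is None:
            self.learning_rate = DEFAULT_LEARNING_RATES.get(self.model, 1e-4)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class EvalRecord:
    epoch: int
    accuracy: float
    macro_f1: float
    loss: float


class Adam:
    """Adaptive-moment optimizer with bias-corrected first/second moments."""

    def __init__(self, params: list[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def mse_episode_loss(scores: Tensor, targets: np.ndarray,
                     reduction: str = "sum") -> Tensor:
    """Squared error between relation scores and 0/1 targets, summed over
    every (class, query) pair (or averaged with ``reduction='mean'``)."""
    if scores.shape != np.asarray(targets).shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs targets "
                         f"{np.asarray(targets).shape}")
    err = scores - np.asarray(targets, float)
    sq = err * err
    if reduction == "sum":
        return sum_(sq)
    if reduction == "mean":
        return sq.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def _episode_loss(model, episode: Episode, train: bool,
                  rng: np.random.Generator | None,
                  reduction: str = "sum") -> Tensor:
    support = episode.support_array()
    query = episode.query_array()
    targets = relation_targets(episode)
    if model.kind == "proto":
        logp = model.episode_log_probs(support, query, train=train, rng=rng)
        idx = episode.query_class_indices()
        picked = logp[np.arange(len(idx)), idx]
        return -sum_(picked) if reduction == "sum" else -picked.mean()
    scores = model.episode_scores(support, query, train=train, rng=rng)
    return mse_episode_loss(scores, targets, reduction)


def evaluate(model, bundle: DatasetBundle, spec: EpisodeSpec, n_episodes: int,
             rng: np.random.Generator,
             pooled: bool = True) -> tuple[float, float, np.ndarray]:
    """Run ``n_episodes`` test episodes and score the predictions.

    ``pooled=True`` pools all (true, predicted) pairs into one confusion
    matrix per call; otherwise per-episode accuracies/F1s are averaged.
    """
    y_true: list[str] = []
    y_pred: list[str] = []
    per_acc, per_f1 = [], []
    for _ in range(n_episodes):
        ep = sample_episode(bundle, spec, rng)
        pred_idx = model.predict(ep.support_array(), ep.query_array())
        truth = [s.label for s in ep.query]
        preds = [ep.class_order[i] for i in pred_idx]
        if pooled:
            y_true.extend(truth)
            y_pred.extend(preds)
        else:
            cm = confusion(truth, preds, ep.class_order)
            per_acc.append(accuracy(cm))
            per_f1.append(macro_f1(cm))
    if pooled:
        cm = confusion(y_true, y_pred, bundle.classes)
        return accuracy(cm), macro_f1(cm), cm
    return float(np.mean(per_acc)), float(np.mean(per_f1)), np.empty((0, 0))


def train_few_shot(bundle_train: DatasetBundle, bundle_test: DatasetBundle,
                   config: TrainConfig):
    """Train a few-shot model episodically; returns (model, history).

    History holds one :class:`EvalRecord` per periodic test.  The run is a
    pure function of ``config`` (including its seed).
    """
    with use_dtype(config.dtype):
        return _train_few_shot(bundle_train, bundle_test, config)


def _train_few_shot(bundle_train: DatasetBundle, bundle_test: DatasetBundle,
                    config: TrainConfig):
    seed_root = np.random.SeedSequence(config.seed)
    init_seq, episode_seq, aug_seq, drop_seq, eval_seq = seed_root.spawn(5)
    model = build_model(config.model, rng=np.random.default_rng(init_seq))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    episode_rng = np.random.default_rng(episode_seq)
    aug_rng = np.random.default_rng(aug_seq)
    drop_rng = np.random.default_rng(drop_seq)
    history: list[EvalRecord] = []
    for epoch in range(config.epochs):
        episode = sample_episode(bundle_train, config.spec, episode_rng)
        if config.shuffle_channels:
            episode = _shuffle_episode(episode, aug_rng)
        opt.zero_grad()
        loss = _episode_loss(model, episode, train=True, rng=drop_rng,
                             reduction=config.loss_reduction)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {loss.data!r}; "
                "lower the learning rate or inspect the input bundles")
        loss.backward()
        opt.step()
        if epoch % config.eval_every == 0:
            eval_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 90001, epoch]))
            acc, f1, _ = evaluate(model, bundle_test, config.spec,
                                  config.test_episodes, eval_rng,
                                  pooled=config.pooled_metrics)
            history.append(EvalRecord(epoch, acc, f1, float(loss.data)))
            logger.info("epoch %d: loss=%.4f accuracy=%.3f macro_f1=%.3f",
                        epoch, float(loss.data), acc, f1)
    return model, history


def _shuffle_episode(episode: Episode, rng: np.random.Generator) -> Episode:
    """One channel permutation applied to ALL samples of the episode."""
    flat = [s for row in episode.support for s in row] + episode.query
    shuffled = channel_shuffle(flat, rng=rng)
    k = len(episode.support[0])
    support = [shuffled[i * k:(i + 1) * k] for i in range(len(episode.support))]
    return replace(episode, support=support,
                   query=shuffled[len(episode.support) * k:])


def aggregate_window(history: list[EvalRecord], epoch_lo: int = 700,
                     epoch_hi: int = 1000) -> RunStatistics:
    """Mean and 95% t-interval half-width of accuracy/F1 over the eval
    records with epoch_lo <= epoch <= epoch_hi (both inclusive)."""
    window = [r for r in history if epoch_lo <= r.epoch <= epoch_hi]
    if not window:
        raise ValueError(f"no eval records in window [{epoch_lo}, {epoch_hi}]")
    return run_statistics([r.accuracy for r in window],
                          [r.macro_f1 for r in window])
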