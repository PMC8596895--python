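"""Training loop: SGD with momentum under a triangular learning-rate schedule.

The schedule rises linearly from 0 to the peak rate over the first
``warmup_fraction`` of optimizer steps and decays linearly back to 0 over
the rest.  Defaults mirror the published recipe: batch 16, 100 epochs,
peak 8e-4, momentum 0.9, 1% warmup.  Gradient clipping (global norm 5) is
on by default — un-scaled attention occasionally produces large score
gradients early in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import SGD
from .corpus import LabeledSentence
from .metrics import evaluate
from .sequence_model import EventTagger

__all__ = ["TrainConfig", "triangular_lr", "train"]


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 100
    peak_lr: float = 0.0008
    momentum: float = 0.9
    warmup_fraction: float = 0.01
    clip_norm: float | None = 5.0
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if not (0.0 < self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.peak_lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and counts must be positive")


def triangular_lr(step: int, total_steps: int, peak: float = 0.0008,
                  warmup_fraction: float = 0.01) -> float:
    """Piecewise-linear LR: 0 -> peak at step w, then back to 0 at the end.

    ``w = round(warmup_fraction * total_steps)``; step is 0-based.
    """
    if not (0 <= step < total_steps):
        raise ValueError(f"step {step} outside [0, {total_steps})")
    w = int(round(warmup_fraction * total_steps))
    if step <= w:
        return peak * step / w if w > 0 else peak
    last = total_steps - 1
    if last == w:
        return peak
    return peak * (last - step) / (last - w)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)       # per epoch mean
    lr: list[float] = field(default_factory=list)         # per step
    dev_strict_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_dev_f1: float = -1.0


def train(corpus: list[LabeledSentence], model: EventTagger,
          config: TrainConfig | None = None,
          dev_corpus: list[LabeledSentence] | None = None) -> TrainHistory:
    """Optimize the model in place; returns the training history.

    When a dev corpus is given, strict F1 is computed each epoch and the
    best-scoring parameters are restored at the end.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), momentum=config.momentum,
              clip_norm=config.clip_norm)
    n_batches = (len(corpus) + config.batch_size - 1) // config.batch_size
    total_steps = config.epochs * n_batches
    history = TrainHistory()
    best_params = None
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus)) if config.shuffle \
            else np.arange(len(corpus))
        epoch_losses = []
        for i in range(0, len(corpus), config.batch_size):
            batch = [corpus[j] for j in order[i:i + config.batch_size]]
            opt.zero_grad()
            # batch-mean NLL keeps gradient scale independent of batch size
            loss = model.loss(batch, rng=rng if model.config.dropout > 0 else None) \
                * (1.0 / len(batch))
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss {value} at epoch {epoch}, step {step}; "
                    "try a lower peak_lr or stronger clipping"
                )
            loss.backward()
            lr = triangular_lr(step, total_steps, config.peak_lr,
                               config.warmup_fraction)
            opt.step(lr)
            history.lr.append(lr)
            epoch_losses.append(value)
            step += 1
        history.loss.append(float(np.mean(epoch_losses)))
        if dev_corpus:
            report = evaluate(dev_corpus, model.predict_corpus(dev_corpus),
                              model.schema)
            history.dev_strict_f1.append(report.strict_f1)
            if report.strict_f1 > history.best_dev_f1:
                history.best_dev_f1 = report.strict_f1
                history.best_epoch = epoch
                best_params = model.copy_params()
    if best_params is not None:
        model.load_params(best_params)
    return history
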