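"""Dataset splitting, training loop, evaluation and the ablation experiments.

Two split policies are provided.  The "paper-faithful" policy splits at the
image-sample level after augmentation — the published protocol — which lets
near-duplicate overlapping windows of one subject fall on both sides of the
split and therefore optimistically biases test accuracy.  The default
"subject-level" policy splits whole subjects before windowing, guaranteeing
zero subject leakage; it is the honest protocol for generalization claims.

The ablation procedures mirror the published experiments on any cohort:
a window-length sweep, a fused-channel-count sweep, and an
augmentation-factor sweep (AU-N vs AU-2/4/8).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from eegfuse.clipping import ClipConfig, expected_sample_count, msc_augment
from eegfuse.nn.metrics import (
    accuracy_score,
    confusion_matrix,
    cross_entropy_loss,
    one_hot,
    softmax_probabilities,
)
from eegfuse.nn.network import ModelConfig, Sequential, build_network
from eegfuse.nn.optim import make_optimizer
from eegfuse.render import ImageSample, RenderConfig, render_dataset
from eegfuse.types import MultichannelRecord


@dataclass(frozen=True)
class SplitPolicy:
    """How to divide image samples into train and test sets.

    mode
        "subject-level" (default): no subject appears on both sides.
        "paper-faithful": seeded stratified shuffle of individual images.
    train_fraction
        Default 0.9 (the published 90/10 division).
    """

    mode: str = "subject-level"
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("subject-level", "paper-faithful"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class EvalReport:
    """Evaluation outcome: accuracy, mean loss, confusion matrix, optional t-SNE."""

    accuracy: float
    loss: float
    confusion: np.ndarray  # k x k, rows = true class
    per_class_counts: np.ndarray
    tsne_coords: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class ExperimentTable:
    """One row per ablation condition: (condition label, loss, accuracy)."""

    condition_name: str
    rows: list[tuple[str, float, float]]
    recommended: str | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=[self.condition_name, "loss", "accuracy"])


def split_dataset(
    samples: list[ImageSample], policy: SplitPolicy
) -> tuple[list[ImageSample], list[ImageSample], list[str]]:
    """Partition samples into (train, test, warnings) under ``policy``.

    Both modes stratify by class; subject-level mode additionally keeps every
    subject's images on one side only (at least one test subject per class
    whenever a class has two or more subjects).
    """
    rng = np.random.default_rng(policy.seed)
    labels = sorted({s.label for s in samples})
    train: list[ImageSample] = []
    test: list[ImageSample] = []
    notes: list[str] = []

    if policy.mode == "paper-faithful":
        for lab in labels:
            group = [s for s in samples if s.label == lab]
            order = rng.permutation(len(group))
            n_train = int(round(policy.train_fraction * len(group)))
            n_train = min(max(n_train, 1), len(group) - 1) if len(group) > 1 else n_train
            for pos, idx in enumerate(order):
                (train if pos < n_train else test).append(group[idx])
            if len(group) < 2:
                notes.append(f"class {lab} has a single sample; test side empty")
    else:
        for lab in labels:
            subjects = sorted({s.subject_id for s in samples if s.label == lab})
            order = rng.permutation(len(subjects))
            n_train = int(round(policy.train_fraction * len(subjects)))
            n_train = min(max(n_train, 1), len(subjects) - 1) if len(subjects) > 1 else n_train
            train_subj = {subjects[i] for i in order[:n_train]}
            if len(subjects) < 2:
                notes.append(f"class {lab} has a single subject; test side empty")
            for s in samples:
                if s.label == lab:
                    (train if s.subject_id in train_subj else test).append(s)

    test_labels = {s.label for s in test}
    for lab in labels:
        if lab not in test_labels:
            notes.append(f"class {lab} absent from test set")
    for msg in notes:
        _warnings.warn(msg, stacklevel=2)
    return train, test, notes


def _to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images to NCHW float32 in [-0.5, 0.5] plus an int label vector."""
    x = np.stack([s.pixels for s in samples]).astype(np.float32) / 255.0 - 0.5
    x = x.transpose(0, 3, 1, 2)
    y = np.array([s.label for s in samples], dtype=int)
    return x, y


def train(
    net: Sequential,
    train_samples: list[ImageSample],
    config: ModelConfig,
) -> list[dict[str, float]]:
    """Minibatch training minimizing cross-entropy; returns per-epoch history.

    Fully seeded: weight init comes from ``build_network(config)`` and epoch
    shuffling from ``config.seed``, so the loss history is reproducible on a
    given machine in single-threaded mode.
    """
    if not train_samples:
        raise ValueError("training set is empty")
    x, y = _to_arrays(train_samples)
    if x.shape[2] != config.input_size or x.shape[3] != config.input_size:
        raise ValueError(
            f"images are {x.shape[2]}x{x.shape[3]} but the network expects "
            f"{config.input_size}x{config.input_size}"
        )
    y_onehot = one_hot(y, config.n_classes)
    rng = np.random.default_rng(config.seed + 1)
    opt = make_optimizer(config.optimizer, config.learning_rate)
    n = len(train_samples)
    history: list[dict[str, float]] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = net.forward(x[idx], train=True)
            probs = softmax_probabilities(logits)
            loss = cross_entropy_loss(probs, y_onehot[idx])
            grad = ((probs - y_onehot[idx]) / len(idx)).astype(np.float32)
            net.backward(grad)
            opt.step(net.layers)
            epoch_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"epoch": epoch + 1, "loss": epoch_loss / n, "accuracy": correct / n}
        )
    return history


def _predict(net: Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for lo in range(0, len(x), batch_size):
        out.append(softmax_probabilities(net.forward(x[lo : lo + batch_size])))
    return np.concatenate(out, axis=0)


def evaluate(
    net: Sequential,
    test_samples: list[ImageSample],
    n_classes: int,
    with_tsne: bool = False,
    tsne_seed: int = 0,
) -> EvalReport:
    """Accuracy, mean cross-entropy and confusion matrix on the test set.

    With ``with_tsne`` the penultimate-layer activations are embedded in 2-D
    by t-SNE (perplexity min(30, n/4), seeded); skipped with a notice when
    the test set is too small for the perplexity constraint.
    """
    if not test_samples:
        raise ValueError("test set is empty")
    x, y = _to_arrays(test_samples)
    probs = _predict(net, x)
    pred = probs.argmax(axis=1)
    report = EvalReport(
        accuracy=accuracy_score(pred, y),
        loss=cross_entropy_loss(probs, one_hot(y, n_classes)),
        confusion=confusion_matrix(y, pred, n_classes),
        per_class_counts=np.bincount(y, minlength=n_classes),
    )
    if with_tsne:
        perplexity = min(30.0, max(2.0, len(test_samples) / 4))
        if len(test_samples) <= perplexity + 1:
            report.warnings.append(
                f"t-SNE skipped: {len(test_samples)} samples <= perplexity {perplexity}"
            )
        else:
            from sklearn.manifold import TSNE

            feats = []
            for lo in range(0, len(x), 64):
                feats.append(net.features(x[lo : lo + 64]))
            report.tsne_coords = TSNE(
                n_components=2,
                perplexity=perplexity,
                max_iter=1000,
                random_state=tsne_seed,
                init="pca",
            ).fit_transform(np.concatenate(feats, axis=0))
    return report


def _run_condition(
    records: list[MultichannelRecord],
    clip_config: ClipConfig,
    render_config: RenderConfig,
    model_config: ModelConfig,
    policy: SplitPolicy,
    channel_subset: list[str] | None = None,
) -> tuple[float, float, EvalReport]:
    """Clip -> render -> split -> train -> evaluate; returns (loss, accuracy, report)."""
    segments = [seg for rec in records for seg in msc_augment(rec, clip_config)]
    images = render_dataset(records, segments, render_config, channel_subset)
    train_set, test_set, _ = split_dataset(images, policy)
    _, net = build_network(model_config)
    train(net, train_set, model_config)
    report = evaluate(net, test_set, model_config.n_classes)
    return report.loss, report.accuracy, report


def run_length_experiment(
    records: list[MultichannelRecord],
    lengths: list[int],
    model_config: ModelConfig,
    render_config: RenderConfig | None = None,
    policy: SplitPolicy | None = None,
    channel_subset: list[str] | None = None,
) -> ExperimentTable:
    """Window-length sweep (AU-N per length); recommends the accuracy argmax.

    Ties break toward the smaller window (smaller windows give more samples
    from the same data). Lengths longer than the shortest record are skipped
    with a note in the table.
    """
    if len(lengths) < 2:
        raise ValueError("need at least 2 candidate lengths")
    if len(set(lengths)) != len(lengths):
        raise ValueError("candidate lengths must be distinct")
    render_config = render_config or RenderConfig(width=64, height=64)
    policy = policy or SplitPolicy()
    min_n = min(r.n_samples for r in records)
    rows = []
    best: tuple[float, int] | None = None
    for X in lengths:
        if X > min_n:
            rows.append((f"{X} (skipped: exceeds shortest record)", float("nan"), float("nan")))
            continue
        loss, acc, _ = _run_condition(
            records, ClipConfig(X, 1), render_config, model_config, policy, channel_subset
        )
        rows.append((str(X), loss, acc))
        if best is None or acc > best[0] or (acc == best[0] and X < best[1]):
            best = (acc, X)
    return ExperimentTable("window_length", rows, recommended=str(best[1]) if best else None)


def run_channel_experiment(
    records: list[MultichannelRecord],
    channel_subsets: list[list[str]],
    model_config: ModelConfig,
    clip_config: ClipConfig | None = None,
    render_config: RenderConfig | None = None,
    policy: SplitPolicy | None = None,
) -> ExperimentTable:
    """Fused-channel-count sweep (e.g. [Fp1], [Fp1, Fp2], [Fp1, Fpz, Fp2])."""
    if not channel_subsets:
        raise ValueError("need at least one channel subset")
    clip_config = clip_config or ClipConfig()
    render_config = render_config or RenderConfig(width=64, height=64)
    policy = policy or SplitPolicy()
    rows = []
    for subset in channel_subsets:
        loss, acc, _ = _run_condition(
            records, clip_config, render_config, model_config, policy, subset
        )
        rows.append((f"{len(subset)}-channel ({','.join(subset)})", loss, acc))
    return ExperimentTable("channels", rows)


def run_augmentation_experiment(
    records: list[MultichannelRecord],
    factors: list[int],
    model_config: ModelConfig,
    window_length: int = 2100,
    render_config: RenderConfig | None = None,
    policy: SplitPolicy | None = None,
    channel_subset: list[str] | None = None,
) -> ExperimentTable:
    """Augmentation-factor sweep: AU-N (factor 1) vs AU-C for each factor."""
    if not factors:
        raise ValueError("need at least one augmentation factor")
    render_config = render_config or RenderConfig(width=64, height=64)
    policy = policy or SplitPolicy()
    rows = []
    for C in factors:
        loss, acc, _ = _run_condition(
            records,
            ClipConfig(window_length, C),
            render_config,
            model_config,
            policy,
            channel_subset,
        )
        label = "AU-N" if C == 1 else f"AU-{C}"
        rows.append((label, loss, acc))
    return ExperimentTable("augmentation", rows)
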