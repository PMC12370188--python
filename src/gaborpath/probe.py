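"""Linear contour-detection readouts over backbone layers.

A readout is a two-output linear head ("contour absent" / "contour present")
trained with softmax cross-entropy on the flattened activations of one
registered probe point, either with the backbone frozen or fine-tuned
end-to-end. The optimization recipe is SGD with momentum 0.9, no weight
decay, batch size 8, and a one-cycle learning-rate schedule with maximum
learning rate 1e-4 and a 40% rising fraction (AdamW is available for the
vernier protocol). Accuracy on a held-out test set is reported with a
normal-approximation 95% confidence interval and a per-curvature breakdown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn, stimuli

__all__ = [
    "ProbeConfig",
    "EvalReport",
    "ContourDataset",
    "make_contour_dataset",
    "extract_activations",
    "train_readout",
    "evaluate",
    "layer_sweep",
]


@dataclass(frozen=True)
class ProbeConfig:
    layer: str = "avgpool"
    mode: str = "frozen"  # frozen | finetune
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    epochs: int = 100
    pct_start: float = 0.4
    optimizer: str = "sgd"  # sgd | adamw
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("frozen", "finetune"):
            raise ValueError("mode must be 'frozen' or 'finetune'")


@dataclass
class EvalReport:
    accuracy: float
    ci95_low: float
    ci95_high: float
    n: int
    per_beta: pd.DataFrame | None = None


@dataclass
class ContourDataset:
    """In-memory stimulus set: one row per image."""
    images: np.ndarray  # (N, H, W)
    labels: np.ndarray  # 1 = contour present
    pair_ids: np.ndarray
    betas: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def check_balanced(self, tol: float = 0.1) -> None:
        frac = self.labels.mean()
        if len(self) == 0:
            raise ValueError("empty dataset")
        if abs(frac - 0.5) > tol:
            raise ValueError(f"class imbalance: present fraction {frac:.3f}")


def make_contour_dataset(betas, pairs_per_beta: int, seed: int,
                         gabor: stimuli.GaborParams = stimuli.DESK_GABOR,
                         grid: stimuli.GridSpec = stimuli.DESK_GRID,
                         path_params: stimuli.PathParams = stimuli.DESK_PATH,
                         jitter: float = 0.0) -> ContourDataset:
    """Render a balanced present/absent set (desk-scale defaults). With
    ``jitter`` > 0, contour elements are displaced perpendicular to the path
    after generation (the alignment-jitter manipulation)."""
    images, labels, pids, bs = [], [], [], []
    for beta in betas:
        for i in range(pairs_per_beta):
            ps = stimuli._pair_seed(seed, beta, i)
            pair = stimuli.render_pair(beta, ps, gabor=gabor, grid=grid,
                                       path_params=path_params)
            if jitter > 0:
                jr = np.random.default_rng(ps + 1)
                for _ in range(20):
                    try:
                        pair = stimuli.apply_alignment_jitter(pair, jitter, jr)
                        break
                    except stimuli.PathGenerationError:
                        pair = stimuli.render_pair(beta, ps + 7919, gabor=gabor,
                                                   grid=grid,
                                                   path_params=path_params)
            pid = f"s{seed}_b{beta:g}_p{i:05d}"
            for label, img in ((1, pair.present_image), (0, pair.absent_image)):
                images.append(img)
                labels.append(label)
                pids.append(pid)
                bs.append(beta)
    return ContourDataset(np.array(images), np.array(labels),
                          np.array(pids), np.array(bs, dtype=float))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _as_batch(images: np.ndarray) -> np.ndarray:
    if images.ndim == 3:
        return images[:, None, :, :]
    return images


def extract_activations(model: nn.Sequential, layer: str, images: np.ndarray,
                        batch_size: int = 32) -> np.ndarray:
    """Flattened activations of ``layer`` for each image (eval mode)."""
    x = _as_batch(images)
    outs = []
    for i in range(0, len(x), batch_size):
        a = model.forward(x[i:i + batch_size], upto=layer)
        outs.append(a.reshape(a.shape[0], -1))
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _split_by_pair(pair_ids: np.ndarray, val_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    unique = np.unique(pair_ids)
    rng.shuffle(unique)
    n_val = int(round(val_fraction * len(unique)))
    val_ids = set(unique[:n_val].tolist())
    val_mask = np.array([p in val_ids for p in pair_ids])
    return ~val_mask, val_mask


def _make_optimizer(config: ProbeConfig, params):
    if config.optimizer == "adamw":
        return nn.AdamW(params, weight_decay=config.weight_decay)
    return nn.SGD(params, momentum=config.momentum,
                  weight_decay=config.weight_decay)


def train_readout(model: nn.Sequential, dataset: ContourDataset,
                  config: ProbeConfig) -> nn.Linear:
    """Train the two-way linear head on ``config.layer``.

    Frozen mode extracts features once and leaves the backbone bit-identical;
    finetune mode backpropagates through the backbone and updates it in
    place. Returns the trained head.
    """
    dataset.check_balanced()
    rng = np.random.default_rng(config.seed)
    train_mask, _ = _split_by_pair(dataset.pair_ids, config.val_fraction, rng)
    images = _as_batch(dataset.images)[train_mask]
    labels = dataset.labels[train_mask]

    frozen = config.mode == "frozen"
    if frozen:
        feats = extract_activations(model, config.layer, images[:, 0])
        dim = feats.shape[1]
    else:
        probeshape = model.forward(images[:1], upto=config.layer).shape
        dim = int(np.prod(probeshape[1:]))

    head = nn.Linear(dim, 2, seed=config.seed)
    params = head.parameters() + ([] if frozen else model.parameters())
    opt = _make_optimizer(config, params)

    n = len(labels)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            lr = nn.one_cycle_lr(step, total_steps, config.learning_rate,
                                 pct_start=config.pct_start)
            if frozen:
                z = head.forward(feats[idx])
                _, dz = nn.cross_entropy(z, labels[idx])
                head.backward(dz)
                grads = head.gradients()
            else:
                a = model.forward(images[idx], upto=config.layer,
                                  train=True, rng=rng)
                z = head.forward(a.reshape(a.shape[0], -1))
                _, dz = nn.cross_entropy(z, labels[idx])
                dfeat = head.backward(dz)
                model.backward(dfeat.reshape(a.shape))
                grads = head.gradients() + model.gradients()
            if config.learning_rate > 0:
                opt.step(grads, lr)
            step += 1
    return head


def predict(head: nn.Linear, model: nn.Sequential, layer: str,
            images: np.ndarray) -> np.ndarray:
    feats = extract_activations(model, layer, images)
    return head.forward(feats).argmax(axis=1)


def contour_logits(head: nn.Linear, model: nn.Sequential, layer: str,
                   images: np.ndarray) -> np.ndarray:
    """Raw activations of the two output nodes (column 1 = contour present)."""
    feats = extract_activations(model, layer, images)
    return head.forward(feats)


def evaluate(head: nn.Linear, model: nn.Sequential, layer: str,
             test: ContourDataset,
             train_pair_ids: np.ndarray | None = None) -> EvalReport:
    """Accuracy with a normal-approximation 95% CI over per-image
    correctness, plus a per-curvature breakdown. Raises on train/test
    pair-id leakage when training ids are supplied."""
    if train_pair_ids is not None:
        overlap = set(np.unique(train_pair_ids)) & set(np.unique(test.pair_ids))
        if overlap:
            raise ValueError(f"train/test pair-id leakage: {sorted(overlap)[:5]}")
    pred = predict(head, model, layer, test.images)
    correct = (pred == test.labels).astype(float)
    n = len(correct)
    acc = float(correct.mean())
    se = float(correct.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    per_beta = (pd.DataFrame({"beta_deg": test.betas, "correct": correct})
                .groupby("beta_deg")["correct"]
                .agg(accuracy="mean", n="count").reset_index())
    return EvalReport(accuracy=acc, ci95_low=acc - 1.96 * se,
                      ci95_high=acc + 1.96 * se, n=n, per_beta=per_beta)


def layer_sweep(model_factory, layers, train: ContourDataset,
                test: ContourDataset, config: ProbeConfig,
                modes=("frozen",)) -> pd.DataFrame:
    """Accuracy table over layer x mode. ``model_factory()`` must return a
    fresh backbone so fine-tuning one layer cannot contaminate the next."""
    rows = []
    for mode in modes:
        for layer in layers:
            model = model_factory()
            cfg = replace(config, layer=layer, mode=mode)
            head = train_readout(model, train, cfg)
            rep = evaluate(head, model, layer, test,
                           train_pair_ids=train.pair_ids)
            rows.append({"layer": layer, "mode": mode,
                         "accuracy": rep.accuracy, "ci95_low": rep.ci95_low,
                         "ci95_high": rep.ci95_high, "n": rep.n})
    return pd.DataFrame(rows)
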