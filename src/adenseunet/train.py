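"""Training loop, evaluation and prediction.

Protocol: Adam starting at lr 0.01, learning rate divided by 10 after 5
epochs without validation-loss improvement (min-delta 1e-4), early stopping
on the validation set, batch size 10, binary cross-entropy by default
(soft Dice, soft Jaccard and MSE are selectable).  The loss is averaged
over pixels and batch so the learning rate is stable across image sizes.
The best-validation parameter state is retained and restored at the end.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import metrics as M
from . import nn
from .arch import ADenseUNet, build_model
from .config import ModelConfig, TrainConfig
from .nn import functional as F
from .nn.tensor import Tensor
from .phantom import SegmentationSample

_ABLATION_FLAGS = {
    "no_attention": "use_attention",
    "no_dilation": "use_dilation",
    "no_dense_links": "use_dense_decoder_links",
}


def ablate(model_config: ModelConfig, flags: list[str]) -> ModelConfig:
    """Return a copy of the config with the named components disabled."""
    unknown = set(flags) - set(_ABLATION_FLAGS)
    if unknown:
        raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
    cfg = copy.deepcopy(model_config)
    for flag in flags:
        setattr(cfg, _ABLATION_FLAGS[flag], False)
    return cfg


# ---------------------------------------------------------------------------
# losses on autodiff tensors
# ---------------------------------------------------------------------------


def _bce(pred: Tensor, truth: Tensor) -> Tensor:
    p = F.clip(pred, M.EPS_CLIP, 1.0 - M.EPS_CLIP)
    one_minus = F.add(F.neg(p), Tensor(np.float32(1.0)))
    one_minus_y = F.add(F.neg(truth), Tensor(np.float32(1.0)))
    ll = F.add(F.mul(truth, F.log(p)), F.mul(one_minus_y, F.log(one_minus)))
    return F.neg(F.tmean(ll))


def _soft_overlap(pred: Tensor, truth: Tensor) -> tuple[Tensor, Tensor]:
    inter = F.tsum(F.mul(pred, truth))
    total = F.add(F.tsum(pred), F.tsum(truth))
    return inter, total


def _dice_loss(pred: Tensor, truth: Tensor, smooth: float = 1.0) -> Tensor:
    inter, total = _soft_overlap(pred, truth)
    num = F.add(F.scale(inter, 2.0), Tensor(np.float32(smooth)))
    den = F.add(total, Tensor(np.float32(smooth)))
    # 1 - num/den  computed as  1 + (-num) * den^-1  via log-free reciprocal
    return F.add(Tensor(np.float32(1.0)), F.neg(_div(num, den)))


def _jaccard_loss(pred: Tensor, truth: Tensor, smooth: float = 1.0) -> Tensor:
    inter, total = _soft_overlap(pred, truth)
    union = F.add(total, F.neg(inter))
    num = F.add(inter, Tensor(np.float32(smooth)))
    den = F.add(union, Tensor(np.float32(smooth)))
    return F.add(Tensor(np.float32(1.0)), F.neg(_div(num, den)))


def _div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g / b.data)
        if b.requires_grad:
            b.accumulate_grad(-g * a.data / (b.data**2))

    from .nn.tensor import make_output

    return make_output(data, (a, b), backward)


def _mse(pred: Tensor, truth: Tensor) -> Tensor:
    d = F.sub(pred, truth)
    return F.tmean(F.mul(d, d))


LOSSES = {"bce": _bce, "dice": _dice_loss, "jaccard": _jaccard_loss, "mse": _mse}


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------


def _to_batch(samples: list[SegmentationSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    y = np.stack([s.mask[None, :, :] for s in samples]).astype(np.float32)
    return x, y


def _forward_probs(model: ADenseUNet, samples: list[SegmentationSample],
                   batch_size: int = 8) -> list[np.ndarray]:
    """Inference-mode probability maps, one (H, W) array per sample."""
    model.eval()
    probs = []
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            x, _ = _to_batch(samples[i : i + batch_size])
            out = model(x).data
            probs.extend(out[j, 0] for j in range(out.shape[0]))
    return probs


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_samples: list[SegmentationSample],
    val_samples: list[SegmentationSample] | None = None,
    verbose: bool = False,
) -> tuple[ADenseUNet, dict]:
    """Train a model; returns (best model, history).

    History records per-epoch training loss, learning rate, and validation
    loss/Dice/IoU when a validation set is given.  All randomness (init,
    shuffling) derives from the two config seeds.
    """
    train_config.validate()
    if not train_samples:
        raise ValueError("empty training set")
    model = build_model(model_config, seed=model_config.seed)
    optimizer = nn.Adam(model.parameters(), lr=train_config.initial_lr)
    loss_fn = LOSSES[train_config.loss]
    shuffle_rng = np.random.default_rng(train_config.seed)

    history: dict = {"train_loss": [], "lr": [], "val_loss": [], "val_dice": [],
                     "val_iou": [], "steps": 0}
    best_val = np.inf
    best_state = model.get_state()
    plateau_wait = 0
    stop_wait = 0
    lr = train_config.initial_lr
    stop = False

    for _epoch in range(train_config.epochs):
        model.train()
        order = shuffle_rng.permutation(len(train_samples))
        epoch_losses = []
        for i in range(0, len(order), train_config.batch_size):
            batch = [train_samples[j] for j in order[i : i + train_config.batch_size]]
            x, y = _to_batch(batch)
            pred = model(x)
            loss = loss_fn(pred, Tensor(y))
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at step {history['steps']}: {loss.item()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            history["steps"] += 1
            if (
                train_config.max_steps is not None
                and history["steps"] >= train_config.max_steps
            ):
                stop = True
                break
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(lr)

        if val_samples:
            probs = _forward_probs(model, val_samples, train_config.batch_size)
            truths = [s.mask for s in val_samples]
            val_loss = float(
                np.mean([M.bce_loss(p, t) for p, t in zip(probs, truths)])
            )
            rep = M.evaluate_dataset(probs, truths)
            history["val_loss"].append(val_loss)
            history["val_dice"].append(rep.dice)
            history["val_iou"].append(rep.iou)
            monitored = val_loss
        else:
            monitored = history["train_loss"][-1]

        if monitored < best_val - train_config.plateau_min_delta:
            best_val = monitored
            best_state = model.get_state()
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait > train_config.plateau_patience:
                lr *= train_config.plateau_factor
                optimizer.lr = lr
                plateau_wait = 0
            if stop_wait >= train_config.early_stop_patience:
                stop = True
        if verbose:
            print(
                f"epoch {_epoch}: loss {history['train_loss'][-1]:.4f} lr {lr:g}",
                flush=True,
            )
        if stop:
            break

    model.set_state(best_state)
    model.eval()
    if train_config.checkpoint_dir:
        save_checkpoint(model, Path(train_config.checkpoint_dir) / "best.npz")
        (Path(train_config.checkpoint_dir) / "history.json").write_text(
            json.dumps({k: v for k, v in history.items()}, indent=2)
        )
    return model, history


# ---------------------------------------------------------------------------
# checkpointing (flat .npz of the state arrays + the config)
# ---------------------------------------------------------------------------


def save_checkpoint(model: ADenseUNet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    cfg = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in dataclasses.asdict(model.config).items()}
    )
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ADenseUNet:
    from .config import config_from_dict

    with np.load(Path(path)) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg = config_from_dict(ModelConfig, json.loads(cfg_json))
        model = build_model(cfg)
        n = len(model.state_arrays())
        model.set_state([data[f"arr_{i}"] for i in range(n)])
    model.eval()
    return model


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------


def evaluate(
    model: ADenseUNet,
    samples: list[SegmentationSample],
    threshold: float = 0.5,
    aggregation: str = "per-image-mean",
    batch_size: int = 8,
) -> M.MetricsReport:
    """Forward, binarize at ``threshold`` and compute Dice/IoU/recall/precision."""
    probs = _forward_probs(model, samples, batch_size)
    return M.evaluate_dataset(probs, [s.mask for s in samples], threshold, aggregation)


def predict(
    model: ADenseUNet, image: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded binary mask for one H x W x 3 image."""
    x = image.transpose(2, 0, 1)[None].astype(np.float32)
    model.eval()
    with nn.no_grad():
        prob = model(x).data[0, 0]
    return prob, M.binarize(prob, threshold)


def write_prediction(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) * 255).astype(np.uint8))
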