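"""Training and inference for the MobileViT-style classifier."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from ..encoder import EncodedImage
from .autograd import Tensor, cross_entropy
from .layers import Adam
from .mobilevit import PLANS, MobileViT, plan_downsampling

__all__ = ["ViTConfig", "small_vit_config", "prepare_images", "train",
           "predict", "predict_labels", "save_model", "load_model",
           "EnsembleModel"]


@dataclass
class ViTConfig:
    """Classifier hyperparameters.

    Defaults follow the reference acquisition protocol (256 x 256 inputs, batch 16,
    learning rate 1e-3, 10 epochs, global-average-pool head).  The
    reduced configuration :func:`small_vit_config` — 32 x 32 inputs
    cropped to the drawing band, the 'small' plan, a flatten head and a
    cosine-decayed learning rate over 40 epochs — is what the default
    pipeline trains with so a full run stays in CPU-minutes.
    """

    input_size: int = 256
    n_classes: int = 2
    batch_size: int = 16
    learning_rate: float = 1.0e-3
    epochs: int = 10
    patch_h: int = 2
    patch_w: int = 2
    channel_plan: str = "xxs"
    head: str = "avg"                     # "avg" | "flatten"
    lr_schedule: str = "constant"         # "constant" | "cosine"
    warmup_epochs: int = 0                # linear ramp before the schedule
    crop_box: tuple | None = None         # fractional (x0, y0, x1, y1)
    n_restarts: int = 1                   # independently trained members
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.channel_plan not in PLANS:
            raise ValueError(f"unknown channel plan {self.channel_plan!r}")
        if self.head not in ("avg", "flatten"):
            raise ValueError("head must be 'avg' or 'flatten'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must lie in [0, epochs)")
        if self.crop_box is not None:
            self.crop_box = tuple(float(v) for v in self.crop_box)
        down = plan_downsampling(PLANS[self.channel_plan]())
        if self.input_size % (down * self.patch_h) or \
           self.input_size % (down * self.patch_w):
            raise ValueError(
                f"input_size {self.input_size} not divisible by total "
                f"downsampling x patch size ({down} x {self.patch_h})"
            )


def small_vit_config(**overrides) -> ViTConfig:
    """The reduced configuration the default pipeline trains with.

    Crops the encoder's drawing band (where all polylines live) before
    resizing to 32 x 32, keeps canvas position through a flatten head,
    warms the learning rate up over 5 epochs then anneals it to zero
    over 40 cheap epochs, and averages a 3-restart ensemble.
    """
    from ..encoder import EncoderConfig

    defaults = dict(
        input_size=32,
        channel_plan="small",
        head="flatten",
        lr_schedule="cosine",
        learning_rate=2.0e-3,
        warmup_epochs=5,
        epochs=40,
        n_restarts=3,
        crop_box=EncoderConfig().band_crop_fractions(),
    )
    defaults.update(overrides)
    if "warmup_epochs" not in overrides:
        defaults["warmup_epochs"] = min(5, defaults["epochs"] - 1)
    return ViTConfig(**defaults)


def prepare_images(
    images: list[EncodedImage],
    input_size: int,
    crop_box: tuple | None = None,
) -> np.ndarray:
    """Crop (optional), bilinear-resize to a square, scale pixels to [0, 1].

    An image already at ``input_size`` x ``input_size`` is taken as-is:
    it is treated as pre-processed (the pipeline downsamples rasters as
    they are encoded), so the crop is never applied twice.
    """
    out = np.empty((len(images), input_size, input_size, 3), dtype=np.float32)
    for i, img in enumerate(images):
        if img.width == input_size and img.height == input_size:
            out[i] = img.pixels.astype(np.float32) / 255.0
            continue
        pil = img.to_pil()
        if crop_box is not None:
            w, h = pil.size
            x0, y0, x1, y1 = crop_box
            pil = pil.crop((round(x0 * w), round(y0 * h),
                            round(x1 * w), round(y1 * h)))
        pil = pil.resize((input_size, input_size), Image.BILINEAR)
        out[i] = np.asarray(pil, dtype=np.float32) / 255.0
    return out


class EnsembleModel:
    """Averaged-probability ensemble of independently trained members.

    ``logits`` returns the log of the member-mean softmax, so any code
    applying a softmax or argmax downstream sees the averaged ensemble
    prediction.
    """

    def __init__(self, members: list[MobileViT]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def set_training(self, flag: bool) -> None:
        for m in self.members:
            m.set_training(flag)

    def logits(self, images: np.ndarray) -> np.ndarray:
        probs = None
        for m in self.members:
            z = m.logits(images)
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            probs = p if probs is None else probs + p
        return np.log(probs / len(self.members) + 1e-12)


def _train_single(x: np.ndarray, y: np.ndarray, config: ViTConfig,
                  seed: int, restart: int) -> tuple[MobileViT, list[dict]]:
    model = _build_model(ViTConfig(**{**vars(config), "seed": seed}))
    optim = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    n = len(y)
    for epoch in range(1, config.epochs + 1):
        if config.warmup_epochs and epoch <= config.warmup_epochs:
            optim.lr = config.learning_rate * epoch / config.warmup_epochs
        elif config.lr_schedule == "cosine":
            tail = config.epochs - config.warmup_epochs
            optim.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - config.warmup_epochs - 1) / tail)
            )
        model.set_training(True)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model(Tensor(x[idx]))
            loss = cross_entropy(logits, y[idx])
            optim.zero_grad()
            loss.backward()
            optim.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history.append({
            "restart": restart,
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / n,
        })
    model.set_training(False)
    return model, history


def train(
    images: list[EncodedImage],
    config: ViTConfig | None = None,
) -> tuple["MobileViT | EnsembleModel", list[dict]]:
    """Fit the classifier by Adam on softmax cross-entropy.

    The seed fixes parameter initialisation and epoch shuffling, so a
    rerun with identical inputs reproduces the final loss exactly.
    With ``n_restarts > 1`` the run is repeated from seeds
    ``seed, seed+1, ...`` and an averaged-probability
    :class:`EnsembleModel` is returned — restart averaging tames the
    optimisation variance of training a small network on few images.
    Returns the model and a per-epoch history of mean training loss and
    accuracy (tagged with the restart index).
    """
    config = config or ViTConfig()
    labels = np.array([img.label for img in images])
    if any(l is None for l in labels):
        raise ValueError("every training image needs a label")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    x = prepare_images(images, config.input_size, config.crop_box)
    y = labels.astype(int)

    members, history = [], []
    for restart in range(config.n_restarts):
        model, h = _train_single(x, y, config, config.seed + restart, restart)
        members.append(model)
        history.extend(h)
    if config.n_restarts == 1:
        return members[0], history
    return EnsembleModel(members), history


def _build_model(config: ViTConfig) -> MobileViT:
    return MobileViT(
        plan=config.channel_plan,
        n_classes=config.n_classes,
        patch=(config.patch_h, config.patch_w),
        seed=config.seed,
        head_mode=config.head,
        input_size=config.input_size,
    )


def predict(
    model: MobileViT,
    images: list[EncodedImage],
    config: ViTConfig | int,
    batch_size: int = 32,
) -> np.ndarray:
    """Per-image class probabilities (rows sum to 1).

    ``config`` may be a full :class:`ViTConfig` (its input size and crop
    are applied) or a bare input size for uncropped images.
    """
    model.set_training(False)
    if isinstance(config, int):
        x = prepare_images(images, config)
    else:
        x = prepare_images(images, config.input_size, config.crop_box)
    probs = []
    for start in range(0, len(images), batch_size):
        logits = model.logits(x[start:start + batch_size])
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append(e / e.sum(axis=1, keepdims=True))
    return np.vstack(probs)


def predict_labels(model: MobileViT, images: list[EncodedImage],
                   config: ViTConfig | int) -> np.ndarray:
    return predict(model, images, config).argmax(axis=1)


def save_model(model, config: ViTConfig, path) -> None:
    """Write all parameters, batch-norm buffers and the config to .npz."""
    import json

    members = model.members if isinstance(model, EnsembleModel) else [model]
    arrays = {}
    for i, member in enumerate(members):
        for key, holder in member.named_state():
            arrays[f"member{i}.{key}"] = (
                holder.data if isinstance(holder, Tensor) else holder
            )
    arrays["__config__"] = np.frombuffer(
        json.dumps(vars(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path):
    """Rebuild the architecture from the stored config and load its state."""
    import json

    data = np.load(path)
    config = ViTConfig(**json.loads(bytes(data["__config__"]).decode()))
    members = []
    for i in range(config.n_restarts):
        member = _build_model(
            ViTConfig(**{**vars(config), "seed": config.seed + i})
        )
        for key, holder in member.named_state():
            stored = data[f"member{i}.{key}"]
            if isinstance(holder, Tensor):
                holder.data = stored.copy()
            else:
                holder[...] = stored
        member.set_training(False)
        members.append(member)
    model = members[0] if config.n_restarts == 1 else EnsembleModel(members)
    return model, config
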