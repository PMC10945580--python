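"""Neurite masking with the 2.5D U-Net.

A stack is cut into chunks of ``depth`` consecutive slices (reflected at
the z boundaries) laterally tiled so that, after stitching, every pixel of
every slice is predicted exactly once.  Training samples random tiles from
labelled stacks, discards near-blank tiles by a mean-intensity threshold,
augments with random flips/rotations each epoch, and minimises
L = L_IoU + L_CE with Adam (default learning rate 0.001), early-stopping
on validation loss.  The resulting probability map is thresholded into a
neurite mask; optionally, regions whose in-plane thickness exceeds a soma
diameter are excised so soma-localised puncta are excluded downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import LabelVolume, VolumetricImage
from .nn import iou_bce_loss
from .unet import UNet25D

__all__ = [
    "NeuriteChunk",
    "NeuriteTrainingConfig",
    "NeuriteModel",
    "extract_chunks",
    "sample_training_patches",
    "train_neurite_model",
    "segment_neurites",
    "split_samples",
]

DEFAULT_DEPTH = 7


@dataclass
class NeuriteChunk:
    """A depth×H×W sub-volume whose centre slice is the prediction target."""

    data: np.ndarray
    center_z: int
    origin: tuple[int, int]

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("chunk must be 3D (depth, H, W)")


def _reflect_indices(center: int, depth: int, n: int) -> np.ndarray:
    """Slice indices around ``center``, mirror-reflected at the boundaries."""
    half = depth // 2
    idx = np.arange(center - half, center + half + 1)
    if n == 1:
        return np.zeros(depth, dtype=int)
    period = 2 * n - 2
    idx = np.mod(idx, period)
    idx = np.where(idx >= n, period - idx, idx)
    return idx


def _tile_positions(extent: int, tile: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent) with a final boundary-aligned tile."""
    if extent <= tile:
        return [0]
    pos = list(range(0, extent - tile, stride))
    if pos[-1] != extent - tile:
        pos.append(extent - tile)
    return pos


def extract_chunks(
    image: VolumetricImage,
    tile: tuple[int, int] | int | None = None,
    stride: int | None = None,
    depth: int = DEFAULT_DEPTH,
    channel: str = "cytoplasmic",
) -> list[NeuriteChunk]:
    """One chunk per (slice, lateral tile) position of the named channel.

    Boundary slices are depth-padded by reflection; lateral tiles overlap
    when the frame is not a multiple of the stride, and stitching keeps
    the first-written value so each pixel is predicted exactly once.
    """
    vol = image.channels.get(channel)
    if vol is None:
        raise ValueError(f"image has no {channel!r} channel")
    Z, Y, X = vol.shape
    if tile is None:
        tile = (Y, X)
    if isinstance(tile, int):
        tile = (tile, tile)
    th = min(tile[0], Y)
    tw = min(tile[1], X)
    if stride is None:
        stride = min(th, tw)
    chunks = []
    for z in range(Z):
        zi = _reflect_indices(z, depth, Z)
        sub = vol[zi]
        for y0 in _tile_positions(Y, th, stride):
            for x0 in _tile_positions(X, tw, stride):
                chunks.append(
                    NeuriteChunk(
                        data=sub[:, y0 : y0 + th, x0 : x0 + tw].astype(float),
                        center_z=z,
                        origin=(y0, x0),
                    )
                )
    return chunks


def sample_training_patches(
    image: VolumetricImage,
    truth: LabelVolume,
    n: int = 200,
    tile: int = 64,
    blank_threshold: float = 0.0,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    channel: str = "cytoplasmic",
):
    """Randomly sample ``n`` chunks with centre-slice labels, then drop blanks.

    Patches whose mean intensity falls below ``blank_threshold`` are
    discarded (mostly-background patches carry no training signal).  If no
    patch survives, an error suggests lowering the threshold.
    """
    vol = image.channels.get(channel)
    if vol is None:
        raise ValueError(f"image has no {channel!r} channel")
    if truth.shape != vol.shape:
        raise ValueError(f"label shape {truth.shape} != image shape {vol.shape}")
    rng = np.random.default_rng(seed)
    Z, Y, X = vol.shape
    th = min(tile, Y)
    tw = min(tile, X)
    out = []
    for _ in range(n):
        z = int(rng.integers(Z))
        y0 = int(rng.integers(Y - th + 1))
        x0 = int(rng.integers(X - tw + 1))
        zi = _reflect_indices(z, depth, Z)
        chunk = vol[zi][:, y0 : y0 + th, x0 : x0 + tw].astype(float)
        if chunk.mean() < blank_threshold:
            continue
        label = truth.data[z, y0 : y0 + th, x0 : x0 + tw].astype(float)
        out.append((NeuriteChunk(chunk, z, (y0, x0)), label))
    if not out:
        raise ValueError(
            "all sampled patches fell below blank_threshold; lower the threshold"
        )
    return out


@dataclass(frozen=True)
class NeuriteTrainingConfig:
    """Training hyperparameters for the neurite U-Net."""

    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20
    tile: int = 64
    patches_per_image: int = 200
    blank_threshold: float = 0.0
    batch_size: int = 8
    base: int = 8
    levels: int = 3
    depth: int = DEFAULT_DEPTH
    augment: bool = True
    seed: int = 0


@dataclass
class NeuriteModel:
    """Trained U-Net plus its configuration, normalisation and history."""

    net: UNet25D
    config: NeuriteTrainingConfig
    history: list[dict] = field(default_factory=list)
    trained: bool = False

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = self.net.state()
        state["config_json"] = json.dumps(asdict(self.config))
        state["history_json"] = json.dumps(self.history)
        state["trained"] = self.trained
        np.savez(path, **state)

    @staticmethod
    def load(path: str | Path) -> "NeuriteModel":
        with np.load(path, allow_pickle=False) as data:
            state = {k: data[k] for k in data.files}
        config = NeuriteTrainingConfig(**json.loads(str(state.pop("config_json"))))
        history = json.loads(str(state.pop("history_json")))
        trained = bool(state.pop("trained"))
        return NeuriteModel(
            net=UNet25D.from_state(state), config=config, history=history, trained=trained
        )


def _normalize_volume(vol: np.ndarray) -> np.ndarray:
    sd = vol.std()
    return (vol - vol.mean()) / (sd if sd > 0 else 1.0)


def _normalized_image(image: VolumetricImage, channel: str) -> VolumetricImage:
    vol = image.channels.get(channel)
    if vol is None:
        raise ValueError(f"image has no {channel!r} channel")
    return VolumetricImage(
        channels={channel: _normalize_volume(vol.astype(float))},
        spacing=image.spacing,
        provenance=image.provenance,
    )


def _augment(chunk, label, rng):
    if rng.random() < 0.5:
        chunk = chunk[:, ::-1, :]
        label = label[::-1, :]
    if rng.random() < 0.5:
        chunk = chunk[:, :, ::-1]
        label = label[:, ::-1]
    k = int(rng.integers(4))
    if k and chunk.shape[1] == chunk.shape[2]:
        chunk = np.rot90(chunk, k, axes=(1, 2))
        label = np.rot90(label, k)
    return np.ascontiguousarray(chunk), np.ascontiguousarray(label)


def _binary_scores(pred: np.ndarray, truth: np.ndarray) -> dict:
    tp = float((pred & truth).sum())
    fp = float((pred & ~truth).sum())
    fn = float((~pred & truth).sum())
    tn = float((~pred & ~truth).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    union = tp + fp + fn
    iou = tp / union if union else 1.0
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return dict(precision=precision, recall=recall, f1=f1, iou=iou, accuracy=accuracy)


def train_neurite_model(
    train_samples: list[tuple[VolumetricImage, LabelVolume]],
    val_samples: list[tuple[VolumetricImage, LabelVolume]] | None = None,
    config: NeuriteTrainingConfig | None = None,
    channel: str = "cytoplasmic",
) -> NeuriteModel:
    """Train the 2.5D U-Net on (image, neurite-truth) pairs.

    Each image contributes ``patches_per_image`` random tiles (blanks
    filtered).  Per epoch, tiles are shuffled, optionally flip/rot90
    augmented and fed in minibatches; validation loss (on held-out samples
    or, absent those, the training tiles) drives early stopping with the
    configured patience.  Entirely deterministic for a fixed seed.
    """
    config = config or NeuriteTrainingConfig()
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)

    def collect(samples, seed_offset):
        chunks, labels = [], []
        for i, (img, truth) in enumerate(samples):
            norm = _normalized_image(img, channel)
            pairs = sample_training_patches(
                norm,
                truth,
                n=config.patches_per_image,
                tile=config.tile,
                blank_threshold=config.blank_threshold,
                depth=config.depth,
                seed=config.seed + seed_offset + i,
                channel=channel,
            )
            chunks.extend(p[0].data for p in pairs)
            labels.extend(p[1] for p in pairs)
        return np.stack(chunks), np.stack(labels)

    Xtr, ytr = collect(train_samples, 0)
    if val_samples:
        Xva, yva = collect(val_samples, 10_000)
    else:
        Xva, yva = Xtr, ytr

    net = UNet25D(depth=config.depth, base=config.base, levels=config.levels, seed=config.seed)
    opt = net.make_optimizer(lr=config.lr)

    best_val = np.inf
    best_weights = net.get_weights()
    history = []
    since_best = 0
    n = len(Xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xtr[idx]
            yb = ytr[idx]
            if config.augment:
                pairs = [_augment(c, l, rng) for c, l in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            logits = net.forward(xb)
            loss, dlogits = iou_bce_loss(logits[:, 0], yb)
            net.backward(dlogits[:, None])
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= n

        val_logits = []
        for start in range(0, len(Xva), config.batch_size):
            val_logits.append(net.forward(Xva[start : start + config.batch_size]))
        vl = np.concatenate(val_logits)[:, 0]
        val_loss, _ = iou_bce_loss(vl, yva)
        scores = _binary_scores(1.0 / (1.0 + np.exp(-vl)) >= 0.5, yva.astype(bool))
        history.append(
            dict(epoch=epoch, train_loss=float(train_loss), val_loss=float(val_loss), **scores)
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    net.set_weights(best_weights)
    return NeuriteModel(net=net, config=config, history=history, trained=True)


def segment_neurites(
    model: NeuriteModel,
    image: VolumetricImage,
    threshold: float = 0.5,
    remove_somata: bool = False,
    soma_diameter: float = 8.0,
    channel: str = "cytoplasmic",
    batch_size: int = 8,
) -> LabelVolume:
    """Predict a neurite mask for a full stack.

    Chunks are predicted tile-by-tile and stitched first-writer-wins, so
    the output covers each voxel exactly once and matches the input shape.
    ``remove_somata`` excises in-plane regions thicker than
    ``soma_diameter`` (voxels), keeping thin neurites while dropping cell
    bodies.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    norm = _normalized_image(image, channel)
    vol = norm.channels[channel]
    Z, Y, X = vol.shape
    chunks = extract_chunks(norm, tile=model.config.tile, depth=model.config.depth, channel=channel)
    prob = np.zeros((Z, Y, X))
    written = np.zeros((Z, Y, X), dtype=bool)
    for start in range(0, len(chunks), batch_size):
        batch = chunks[start : start + batch_size]
        maps = model.net.predict_proba(np.stack([c.data for c in batch]))
        for c, m in zip(batch, maps):
            y0, x0 = c.origin
            h, w = m.shape
            tgt = np.s_[c.center_z, y0 : y0 + h, x0 : x0 + w]
            fresh = ~written[tgt]
            prob[tgt][...] = np.where(fresh, m, prob[tgt])
            written[tgt] = True
    mask = prob > threshold
    if remove_somata:
        mask = _remove_somata(mask, soma_diameter)
    return LabelVolume(mask, kind="neurite_mask")


def _remove_somata(mask: np.ndarray, soma_diameter: float) -> np.ndarray:
    """Excise in-plane regions thicker than the soma diameter.

    Per slice, voxels whose in-plane distance-to-background exceeds the
    soma radius form the soma core; the core dilated by the soma radius is
    removed.  Thin neurites (half-width below the radius) never enter the
    core, so a tube attached to a cell body survives while the body is cut
    out.
    """
    radius = soma_diameter / 2.0
    out = mask.copy()
    for z in range(mask.shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        core = ndimage.distance_transform_edt(sl) > radius
        if not core.any():
            continue
        removal = ndimage.distance_transform_edt(~core) <= radius
        out[z] &= ~removal
    return out


def split_samples(samples: list, ratio: tuple[int, int, int] = (10, 2, 4), seed: int = 0):
    """Shuffle and split into (train, val, test) by the given integer ratio."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    total = sum(ratio)
    n_train = int(round(len(samples) * ratio[0] / total))
    n_val = int(round(len(samples) * ratio[1] / total))
    train = [samples[i] for i in idx[:n_train]]
    val = [samples[i] for i in idx[n_train : n_train + n_val]]
    test = [samples[i] for i in idx[n_train + n_val :]]
    return train, val, test
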