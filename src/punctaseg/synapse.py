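"""Two-layer pixel classification for synaptic puncta.

The segmentation model works in two passes over per-pixel local features
(:mod:`punctaseg.features`).  The first layer is a conventional pixel
classifier trained in two sequential steps: step one uses every positive
pixel plus a small set of negatives sampled from a thin band around the
positives, which keeps the training set tiny but leaves the classifier
prone to false positives; step two therefore predicts over patches ten
times the side of the sampling patches, harvests the negatives the
classifier got wrong (hard negatives) and retrains on the expanded set.
The second layer re-classifies each pixel after appending the first
layer's probability at the pixel's six face neighbours (±1 in z, y, x) to
its feature vector — a pixel next to confidently-synaptic pixels is itself
more likely synaptic, which cleans up ragged single-pixel errors.

Random forest is the default model family; SVM and MLP are available.
Hyperparameters are chosen by grid search with five-fold cross-validation.
When a neurite mask is supplied at prediction time only pixels inside the
mask are classified; everything outside is background by construction,
which both removes off-neurite autofluorescence and cuts runtime.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FeatureBank, FeatureScaler, compute_feature_volumes
from .io import LabelVolume, VolumetricImage

__all__ = [
    "SynapseTrainingConfig",
    "TrainingPatchPlan",
    "TwoLayerModel",
    "compute_patch_side",
    "plan_patches",
    "train_layer1",
    "train_layer2",
    "train_synapse_model",
    "segment_synapses",
    "edit_labels",
]

MODEL_FAMILIES = ("random_forest", "support_vector_machine", "multilayer_perceptron")

#: four preset names mirroring the reporter regimes the pipeline targets
SEGMENTATION_PRESETS = ("grasp_sparse", "grasp_dense", "cla1", "rab3")


@dataclass(frozen=True)
class SynapseTrainingConfig:
    """Knobs of the two-step / two-layer training procedure.

    ``neg_band_voxels`` is the dilation radius (in voxels) of the band
    around positive pixels from which step-one negatives are sampled;
    ``neg_pos_ratio`` the number of sampled negatives per positive.  Step
    two scans patches ``step2_scale`` times the sampling patch side and
    adds at most ``hard_negative_cap`` harvested negatives.  ``harvest``
    selects which mistakes are harvested: ``"false_positive"`` (negatives
    the step-one classifier marks positive — the reading consistent with
    growing the negative set) or ``"false_negative"``.
    """

    family: str = "random_forest"
    neg_band_voxels: int = 2
    neg_pos_ratio: float = 3.0
    step2_scale: int = 10
    harvest: str = "false_positive"
    hard_negative_cap: int = 30000
    cv_folds: int = 5
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}")
        if self.harvest not in ("false_positive", "false_negative"):
            raise ValueError("harvest must be 'false_positive' or 'false_negative'")


_DEFAULT_GRIDS = {
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 16]},
    "support_vector_machine": {"C": [1.0, 10.0]},
    "multilayer_perceptron": {"alpha": [1e-4, 1e-3]},
}


def _make_estimator(family: str, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "support_vector_machine":
        return SVC(probability=True, random_state=seed)
    return MLPClassifier(
        hidden_layer_sizes=(50,), max_iter=500, random_state=seed
    )


def _fit_with_grid(X, y, config: SynapseTrainingConfig):
    grid = config.grid if config.grid is not None else _DEFAULT_GRIDS[config.family]
    est = _make_estimator(config.family, config.seed)
    n_per_class = np.bincount(y.astype(int), minlength=2)
    folds = int(min(config.cv_folds, n_per_class[n_per_class > 0].min()))
    if folds >= 2 and any(len(v) > 1 for v in grid.values()):
        search = GridSearchCV(est, grid, cv=folds, n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    est.set_params(**{k: v[0] for k, v in grid.items()})
    est.fit(X, y)
    return est


def _positive_probability(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


# ---------------------------------------------------------------------------
# patch sampling


@dataclass
class TrainingPatchPlan:
    """Non-overlapping 2D tiles, per slice, that contain positive label pixels."""

    patch_side: int
    shape: tuple[int, int, int]
    kept: list[tuple[int, int, int]]  # (z, y0, x0)

    def pixel_coords(self) -> np.ndarray:
        """All (z, y, x) coordinates covered by kept patches."""
        out = []
        _, Y, X = self.shape
        s = self.patch_side
        for z, y0, x0 in self.kept:
            ys = np.arange(y0, min(y0 + s, Y))
            xs = np.arange(x0, min(x0 + s, X))
            yy, xx = np.meshgrid(ys, xs, indexing="ij")
            zz = np.full(yy.size, z)
            out.append(np.column_stack([zz, yy.ravel(), xx.ravel()]))
        if not out:
            return np.empty((0, 3), dtype=int)
        return np.vstack(out)


def compute_patch_side(label: LabelVolume) -> int:
    """Sampling patch side: twice the square root of the mean 2D label area.

    Connected labels are measured slice-by-slice (8-connectivity in-plane);
    the side is rounded to the nearest integer with a floor of 3.  Raises on
    an empty label.
    """
    areas = []
    structure = np.ones((3, 3), dtype=bool)
    for z in range(label.shape[0]):
        lab, n = ndimage.label(label.data[z], structure=structure)
        if n:
            areas.extend(ndimage.sum(np.ones_like(lab), lab, index=range(1, n + 1)))
    if not areas:
        raise ValueError("label volume has no positive pixels")
    side = int(np.rint(2.0 * np.sqrt(np.mean(areas))))
    return max(side, 3)


def plan_patches(label: LabelVolume, patch_side: int) -> TrainingPatchPlan:
    """Tile each slice into non-overlapping patches; keep those with positives."""
    Z, Y, X = label.shape
    s = patch_side
    kept = []
    for z in range(Z):
        sl = label.data[z]
        if not sl.any():
            continue
        for y0 in range(0, Y, s):
            for x0 in range(0, X, s):
                if sl[y0 : y0 + s, x0 : x0 + s].any():
                    kept.append((z, y0, x0))
    return TrainingPatchPlan(patch_side=s, shape=label.shape, kept=kept)


# ---------------------------------------------------------------------------
# layer 1


@dataclass
class Layer1Result:
    classifier: object
    scaler: FeatureScaler
    patch_side: int
    bank: FeatureBank
    config: SynapseTrainingConfig
    # per-image training pixels and labels, reused to train layer 2
    train_pixels: list[np.ndarray] = field(default_factory=list)
    train_labels: list[np.ndarray] = field(default_factory=list)
    step1_size: int = 0
    step2_size: int = 0


def _step1_pixels(label: LabelVolume, config: SynapseTrainingConfig, rng):
    """All positives plus a band-limited sample of nearby negatives."""
    pos = label.data
    band = ndimage.binary_dilation(pos, iterations=config.neg_band_voxels) & ~pos
    pos_coords = np.argwhere(pos)
    band_coords = np.argwhere(band)
    n_neg = min(len(band_coords), int(round(config.neg_pos_ratio * len(pos_coords))))
    if len(band_coords) and n_neg:
        sel = rng.choice(len(band_coords), size=n_neg, replace=False)
        neg_coords = band_coords[np.sort(sel)]
    else:
        neg_coords = np.empty((0, 3), dtype=int)
    coords = np.vstack([pos_coords, neg_coords])
    y = np.r_[np.ones(len(pos_coords)), np.zeros(len(neg_coords))].astype(int)
    return coords, y


def train_layer1(
    images: list[VolumetricImage],
    labels: list[LabelVolume],
    config: SynapseTrainingConfig | None = None,
    bank: FeatureBank | None = None,
    feature_volumes: list[np.ndarray] | None = None,
) -> Layer1Result:
    """Two-step training of the first-layer pixel classifier.

    Step 1 trains on all positive pixels and negatives sampled within a
    thin dilation band around them.  Step 2 predicts over patches
    ``step2_scale``× the sampling patch side, harvests hard negatives and
    retrains.  The feature scaler is fitted on the step-1 training pixels.
    """
    config = config or SynapseTrainingConfig()
    bank = bank or FeatureBank()
    if not images or len(images) != len(labels):
        raise ValueError("need equal, nonempty lists of images and labels")
    if not any(lbl.data.any() for lbl in labels):
        raise ValueError("no positive pixels in any training label")
    rng = np.random.default_rng(config.seed)
    if feature_volumes is None:
        feature_volumes = [compute_feature_volumes(img, bank) for img in images]

    sides = [compute_patch_side(lbl) for lbl in labels if lbl.data.any()]
    patch_side = int(np.rint(np.mean(sides)))

    per_image_pixels, per_image_y, X_parts = [], [], []
    for img, lbl, fv in zip(images, labels, feature_volumes):
        coords, y = _step1_pixels(lbl, config, rng)
        per_image_pixels.append(coords)
        per_image_y.append(y)
        X_parts.append(fv[:, coords[:, 0], coords[:, 1], coords[:, 2]].T)
    X1 = np.vstack(X_parts)
    y1 = np.concatenate(per_image_y)
    if len(np.unique(y1)) < 2:
        raise ValueError("single-class training set after sampling; adjust band/ratio")

    scaler = FeatureScaler().fit(X1)
    clf = _fit_with_grid(scaler.transform(X1), y1, config)

    # -- step 2: hard-mistake harvesting over 10x patches ----------------
    harvested_pixels, harvested_y = [], []
    for img, lbl, fv in zip(images, labels, feature_volumes):
        if not lbl.data.any():
            harvested_pixels.append(np.empty((0, 3), dtype=int))
            harvested_y.append(np.empty(0, dtype=int))
            continue
        big = plan_patches(lbl, patch_side * config.step2_scale)
        coords = big.pixel_coords()
        Xp = scaler.transform(fv[:, coords[:, 0], coords[:, 1], coords[:, 2]].T)
        pred = clf.predict(Xp).astype(bool)
        truth = lbl.data[coords[:, 0], coords[:, 1], coords[:, 2]]
        if config.harvest == "false_positive":
            wrong = pred & ~truth
        else:
            wrong = ~pred & truth
        idx = np.flatnonzero(wrong)
        if len(idx) > config.hard_negative_cap:
            idx = np.sort(rng.choice(idx, size=config.hard_negative_cap, replace=False))
        harvested_pixels.append(coords[idx])
        harvested_y.append(truth[idx].astype(int))

    X_extra, y_extra = [], []
    for (img, fv), coords, yy in zip(
        zip(images, feature_volumes),
        harvested_pixels,
        harvested_y,
    ):
        if len(coords):
            X_extra.append(fv[:, coords[:, 0], coords[:, 1], coords[:, 2]].T)
            y_extra.append(yy)
    if X_extra:
        X2 = np.vstack([X1] + X_extra)
        y2 = np.concatenate([y1] + y_extra)
    else:
        X2, y2 = X1, y1
    clf = _fit_with_grid(scaler.transform(X2), y2, config)

    # merge per-image training pixels with their harvested additions
    all_pixels, all_y = [], []
    hp_iter = iter(zip(harvested_pixels, harvested_y))
    for i, (coords, y) in enumerate(zip(per_image_pixels, per_image_y)):
        extra = next(hp_iter, (np.empty((0, 3), dtype=int), np.empty(0, dtype=int)))
        all_pixels.append(np.vstack([coords, extra[0]]))
        all_y.append(np.concatenate([y, extra[1]]))

    return Layer1Result(
        classifier=clf,
        scaler=scaler,
        patch_side=patch_side,
        bank=bank,
        config=config,
        train_pixels=all_pixels,
        train_labels=all_y,
        step1_size=len(y1),
        step2_size=len(y2),
    )


# ---------------------------------------------------------------------------
# layer 2

_NEIGHBOR_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]]
)


def _neighbor_probabilities(
    coords: np.ndarray,
    prob_at: dict[tuple[int, int, int], float],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """(n, 6) first-layer probabilities at the six face neighbours.

    Neighbours outside the volume take the centre pixel's probability.
    """
    out = np.empty((len(coords), 6))
    shape_arr = np.asarray(shape)
    for i, c in enumerate(coords):
        center = prob_at[tuple(c)]
        for j, off in enumerate(_NEIGHBOR_OFFSETS):
            n = c + off
            if np.any(n < 0) or np.any(n >= shape_arr):
                out[i, j] = center
            else:
                out[i, j] = prob_at.get(tuple(n), center)
    return out


def _probability_lookup(coords, scaler, clf, fv) -> dict:
    X = scaler.transform(fv[:, coords[:, 0], coords[:, 1], coords[:, 2]].T)
    p = _positive_probability(clf, X)
    return {tuple(c): float(v) for c, v in zip(coords, p)}


def train_layer2(
    images: list[VolumetricImage],
    labels: list[LabelVolume],
    layer1: Layer1Result,
    feature_volumes: list[np.ndarray] | None = None,
):
    """Train the second-layer classifier on neighbour-probability-extended features."""
    config = layer1.config
    bank = layer1.bank
    if feature_volumes is None:
        feature_volumes = [compute_feature_volumes(img, bank) for img in images]
    X_parts, y_parts = [], []
    for img, fv, coords, y in zip(
        images, feature_volumes, layer1.train_pixels, layer1.train_labels
    ):
        if not len(coords):
            continue
        shape = img.shape
        neighbors = (coords[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]).reshape(-1, 3)
        inb = np.all((neighbors >= 0) & (neighbors < np.asarray(shape)), axis=1)
        needed = np.unique(np.vstack([coords, neighbors[inb]]), axis=0)
        prob_at = _probability_lookup(needed, layer1.scaler, layer1.classifier, fv)
        base = layer1.scaler.transform(fv[:, coords[:, 0], coords[:, 1], coords[:, 2]].T)
        nb = _neighbor_probabilities(coords, prob_at, shape)
        X_parts.append(np.hstack([base, nb]))
        y_parts.append(y)
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    return _fit_with_grid(X, y, config)


# ---------------------------------------------------------------------------
# the bundled model


@dataclass
class TwoLayerModel:
    """Both classifier layers plus the scaler and training metadata."""

    layer1: object
    layer2: object
    scaler: FeatureScaler
    bank: FeatureBank
    config: SynapseTrainingConfig
    patch_side: int

    @property
    def family(self) -> str:
        return self.config.family

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TwoLayerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TwoLayerModel):
            raise TypeError(f"{path} does not contain a TwoLayerModel")
        return model


def train_synapse_model(
    images: list[VolumetricImage] | VolumetricImage,
    labels: list[LabelVolume] | LabelVolume,
    family: str = "random_forest",
    seed: int = 0,
    config: SynapseTrainingConfig | None = None,
    bank: FeatureBank | None = None,
) -> TwoLayerModel:
    """Train both layers on one or more (image, label) pairs."""
    if isinstance(images, VolumetricImage):
        images = [images]
    if isinstance(labels, LabelVolume):
        labels = [labels]
    if config is None:
        config = SynapseTrainingConfig(family=family, seed=seed)
    else:
        config = replace(config, family=family, seed=seed)
    bank = bank or FeatureBank()
    fvs = [compute_feature_volumes(img, bank) for img in images]
    l1 = train_layer1(images, labels, config=config, bank=bank, feature_volumes=fvs)
    l2 = train_layer2(images, labels, l1, feature_volumes=fvs)
    return TwoLayerModel(
        layer1=l1.classifier,
        layer2=l2,
        scaler=l1.scaler,
        bank=bank,
        config=config,
        patch_side=l1.patch_side,
    )


def _predict_pixels(
    model: TwoLayerModel,
    image: VolumetricImage,
    coords: np.ndarray,
    fv: np.ndarray,
    use_layer2: bool = True,
    batch: int = 200_000,
) -> np.ndarray:
    """Binary prediction at the given coordinates (two-layer unless disabled)."""
    if not len(coords):
        return np.zeros(0, dtype=bool)
    shape = image.shape
    out = np.zeros(len(coords), dtype=bool)
    for start in range(0, len(coords), batch):
        c = coords[start : start + batch]
        base = model.scaler.transform(fv[:, c[:, 0], c[:, 1], c[:, 2]].T)
        if not use_layer2:
            out[start : start + batch] = _positive_probability(model.layer1, base) >= 0.5
            continue
        neighbors = (c[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]).reshape(-1, 3)
        inb = np.all((neighbors >= 0) & (neighbors < np.asarray(shape)), axis=1)
        needed = np.unique(np.vstack([c, neighbors[inb]]), axis=0)
        prob_at = _probability_lookup(needed, model.scaler, model.layer1, fv)
        nb = _neighbor_probabilities(c, prob_at, shape)
        X = np.hstack([base, nb])
        out[start : start + batch] = _positive_probability(model.layer2, X) >= 0.5
    return out


def segment_synapses(
    model: TwoLayerModel,
    image: VolumetricImage,
    mask: LabelVolume | None = None,
    use_layer2: bool = True,
) -> LabelVolume:
    """Classify pixels into a binary synapse prediction.

    With a neurite ``mask``, only pixels inside the mask are classified and
    everything outside is background, so the prediction is a subset of the
    mask by construction.  Without a mask every pixel in the volume is
    scanned.
    """
    if mask is not None and mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    fv = compute_feature_volumes(image, model.bank)
    if mask is not None:
        coords = np.argwhere(mask.data)
    else:
        Z, Y, X = image.shape
        coords = np.argwhere(np.ones(image.shape, dtype=bool))
    pred = np.zeros(image.shape, dtype=bool)
    flags = _predict_pixels(model, image, coords, fv, use_layer2=use_layer2)
    pred[coords[:, 0], coords[:, 1], coords[:, 2]] = flags
    return LabelVolume(pred, kind="synapse_prediction")


def edit_labels(
    volume: LabelVolume,
    add: np.ndarray | None = None,
    remove: np.ndarray | None = None,
) -> LabelVolume:
    """Apply manual corrections: set ``add`` voxels true, then ``remove`` false.

    Corrected volumes are valid training labels, closing the
    predict → review → retrain loop.  Out-of-bounds edits raise.
    """
    data = volume.data.copy()
    shape = np.asarray(volume.shape)
    for coords, value in ((add, True), (remove, False)):
        if coords is None or len(coords) == 0:
            continue
        coords = np.atleast_2d(np.asarray(coords, dtype=int))
        if np.any(coords < 0) or np.any(coords >= shape[None, :]):
            raise IndexError("edit coordinate out of bounds")
        data[coords[:, 0], coords[:, 1], coords[:, 2]] = value
    return LabelVolume(data, kind=volume.kind)
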