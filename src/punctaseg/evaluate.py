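"""Segmentation benchmarking: IoU scoring, training-size curves and
inter-annotator agreement.

The headline metric is the intersection-over-union (Jaccard index) between
a predicted and a ground-truth label volume.  Two volumes that are both
empty agree perfectly on the absence of signal and score 1.  The
training-size benchmark retrains the synapse model on every combination of
a given size (or a seeded subsample when combinations explode) and scores
the held-out images, per image then averaged — which is how one
demonstrates that a single labelled image suffices.  Inter-annotator
comparison turns k experts' labels of the same images into a pairwise IoU
matrix whose off-diagonal mean serves as the human benchmark.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabelVolume, VolumetricImage
from .synapse import SynapseTrainingConfig, segment_synapses, train_synapse_model

__all__ = [
    "SegmentationScore",
    "compute_iou",
    "score_segmentation",
    "benchmark_training_size",
    "compare_annotators",
]


@dataclass(frozen=True)
class SegmentationScore:
    iou: float
    precision: float
    recall: float
    f1: float
    accuracy: float


def _as_bool(vol) -> np.ndarray:
    return vol.data if isinstance(vol, LabelVolume) else np.asarray(vol, dtype=bool)


def compute_iou(pred, truth) -> float:
    """|pred ∧ truth| / |pred ∨ truth|; both empty → 1 (perfect absence)."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    union = int((p | t).sum())
    if union == 0:
        return 1.0
    return int((p & t).sum()) / union


def score_segmentation(pred, truth) -> SegmentationScore:
    """Foreground-class precision/recall/F1/IoU plus overall pixel accuracy."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    iou = tp / (tp + fp + fn) if tp + fp + fn else 1.0
    accuracy = (tp + tn) / p.size
    return SegmentationScore(iou=iou, precision=precision, recall=recall, f1=f1, accuracy=accuracy)


def benchmark_training_size(
    images: list[VolumetricImage],
    labels: list[LabelVolume],
    sizes: list[int],
    masks: list[LabelVolume] | None = None,
    seed: int = 0,
    combination_cap: int = 50,
    family: str = "random_forest",
    config: SynapseTrainingConfig | None = None,
) -> pd.DataFrame:
    """Held-out IoU as a function of training-set size.

    For each size, trains a fresh two-layer model on every size-combination
    of the dataset (seeded subsample if more than ``combination_cap``) and
    scores the remaining images.  Returns a frame with one row per size:
    mean and SD of per-combination IoU (itself the per-image mean over the
    hold-out set), the pooled-voxel IoU variant for comparison, and the
    number of combinations evaluated.
    """
    n = len(images)
    if len(labels) != n:
        raise ValueError("images and labels length mismatch")
    if max(sizes) >= n:
        raise ValueError("every size must leave at least one hold-out image")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        combos = list(itertools.combinations(range(n), size))
        if len(combos) > combination_cap:
            sel = rng.choice(len(combos), size=combination_cap, replace=False)
            combos = [combos[i] for i in np.sort(sel)]
        ious: list[float] = []
        pooled: list[float] = []
        for combo in combos:
            train_idx = list(combo)
            test_idx = [i for i in range(n) if i not in combo]
            model = train_synapse_model(
                [images[i] for i in train_idx],
                [labels[i] for i in train_idx],
                family=family,
                seed=seed,
                config=config,
            )
            per_image = []
            inter = union = 0
            for i in test_idx:
                mask = masks[i] if masks is not None else None
                pred = segment_synapses(model, images[i], mask=mask)
                per_image.append(compute_iou(pred, labels[i]))
                inter += int((pred.data & labels[i].data).sum())
                union += int((pred.data | labels[i].data).sum())
            ious.append(float(np.mean(per_image)))
            pooled.append(inter / union if union else 1.0)
        rows.append(
            dict(
                train_size=size,
                mean_iou=float(np.mean(ious)),
                sd_iou=float(np.std(ious, ddof=1)) if len(ious) > 1 else 0.0,
                mean_iou_pooled=float(np.mean(pooled)),
                n_combinations=len(combos),
            )
        )
    return pd.DataFrame(rows)


def compare_annotators(label_sets: list[list[LabelVolume]]) -> tuple[np.ndarray, float]:
    """Pairwise IoU between k annotators' labels of the same images.

    ``label_sets[a][i]`` is annotator ``a``'s label of image ``i``.  Entry
    (a, b) of the matrix is the mean over images of IoU(a_i, b_i); the
    benchmark scalar is the mean of the off-diagonal entries.
    """
    k = len(label_sets)
    if k < 2:
        raise ValueError("need at least two annotators")
    n_images = len(label_sets[0])
    if any(len(ls) != n_images for ls in label_sets):
        raise ValueError("annotators labelled different numbers of images")
    matrix = np.eye(k)
    for a, b in itertools.combinations(range(k), 2):
        vals = [compute_iou(label_sets[a][i], label_sets[b][i]) for i in range(n_images)]
        matrix[a, b] = matrix[b, a] = float(np.mean(vals))
    off = matrix[~np.eye(k, dtype=bool)]
    return matrix, float(off.mean())
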