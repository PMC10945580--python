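"""Synthetic fluorescence stacks with known ground truth.

Every downstream stage of the pipeline — neurite masking, two-layer pixel
classification, puncta quantification — is exercised on images from this
generator, so nothing here depends on external data.  A sample emulates a
two-channel confocal stack of a single labelled neuron: the cytoplasmic
channel shows the neurite as a bright tube, the synapse channel shows
puncta as isotropic Gaussian blobs centred on neurite voxels, plus
off-neurite "clutter" blobs that mimic autofluorescence from surrounding
tissue.  Additive Gaussian read noise sits on a constant background.

Four presets mirror the reporter regimes the pipeline is designed around:
small puncta (1–3 voxel radius) at low or high SNR, medium puncta
(3–10 voxels) and diffuse signal (>10 voxels).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    CYTOPLASMIC_CHANNEL,
    SYNAPSE_CHANNEL,
    LabelVolume,
    VolumetricImage,
    write_label,
    write_stack,
    write_swc,
)
from .skeleton import Skeleton

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "PlacementError",
    "PRESETS",
    "preset_spec",
    "generate_sample",
    "generate_dataset",
    "save_sample",
    "load_spec",
]

# half-peak radius of a Gaussian blob with sigma = radius / 2
_HALF_PEAK = np.sqrt(2.0 * np.log(2.0)) / 2.0  # ≈ 0.589 × radius


class PlacementError(RuntimeError):
    """Raised when non-overlapping puncta cannot be placed; carries the count."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} non-overlapping puncta; "
            "reduce n_puncta or radii, or enlarge the volume"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic stack; a spec plus seed is the image.

    Intensities are arbitrary camera units.  ``puncta_peak_intensity`` is the
    absolute peak of a punctum (so contrast over background is
    ``peak - background_level``, and the nominal SNR is
    ``(peak - background) / noise_sd``).
    """

    shape: tuple[int, int, int] = (16, 80, 80)
    neurite_paths: tuple[tuple[tuple[float, float, float], ...], ...] = (
        ((8.0, 12.0, 8.0), (7.0, 40.0, 40.0), (8.0, 68.0, 72.0)),
    )
    neurite_radius: float = 2.0
    n_puncta: int = 20
    puncta_radius_range: tuple[float, float] = (1.0, 3.0)
    puncta_peak_intensity: float = 400.0
    background_level: float = 100.0
    noise_sd: float = 15.0
    n_clutter: int = 5
    snr_preset: str | None = None
    seed: int = 0
    cytoplasmic_peak: float = 350.0
    non_overlapping: bool = True

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        rmin, rmax = self.puncta_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("puncta_radius_range must satisfy 0 < min <= max")
        shape = np.asarray(self.shape)
        for path in self.neurite_paths:
            for pt in path:
                if np.any(np.asarray(pt) < 0) or np.any(np.asarray(pt) >= shape):
                    raise ValueError(f"control point {pt} outside volume {self.shape}")

    @property
    def nominal_snr(self) -> float:
        return (self.puncta_peak_intensity - self.background_level) / self.noise_sd


#: preset regimes; radii follow the small/medium/diffuse pixel-radius bands
PRESETS: dict[str, dict] = {
    "small_low_snr": dict(
        puncta_radius_range=(1.0, 3.0),
        puncta_peak_intensity=160.0,
        noise_sd=20.0,
        n_clutter=6,
    ),
    "small_high_snr": dict(
        puncta_radius_range=(1.0, 3.0),
        puncta_peak_intensity=400.0,
        noise_sd=15.0,
        n_clutter=5,
    ),
    "medium": dict(
        shape=(24, 160, 160),
        neurite_paths=(((12.0, 20.0, 16.0), (11.0, 80.0, 80.0), (12.0, 140.0, 148.0)),),
        neurite_radius=3.0,
        n_puncta=8,
        puncta_radius_range=(3.0, 10.0),
        puncta_peak_intensity=300.0,
        noise_sd=15.0,
        n_clutter=3,
    ),
    "diffuse": dict(
        shape=(32, 160, 160),
        neurite_paths=(((16.0, 20.0, 16.0), (15.0, 80.0, 80.0), (16.0, 140.0, 148.0)),),
        neurite_radius=4.0,
        n_puncta=3,
        puncta_radius_range=(10.5, 14.0),
        puncta_peak_intensity=220.0,
        noise_sd=15.0,
        n_clutter=2,
    ),
}


def preset_spec(name: str, **overrides) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` for a named reporter regime."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    params["snr_preset"] = name
    return SyntheticSpec(**params)


@dataclass
class SyntheticSample:
    """One generated stack with every piece of ground truth attached."""

    image: VolumetricImage
    neurite_truth: LabelVolume
    synapse_truth: LabelVolume
    skeleton_truth: Skeleton
    puncta_truth: list[tuple[tuple[int, int, int], float]]
    spec: SyntheticSpec
    image_id: str = "synthetic"


def _polyline_voxels(paths, shape) -> np.ndarray:
    """Rasterise control polylines to an ordered array of voxel coordinates."""
    pts_all = []
    for path in paths:
        path = np.asarray(path, dtype=float)
        for a, b in zip(path[:-1], path[1:]):
            n = max(2, int(np.ceil(np.linalg.norm(b - a) * 2)))
            seg = a[None, :] + np.linspace(0, 1, n)[:, None] * (b - a)[None, :]
            pts_all.append(seg)
    pts = np.vstack(pts_all)
    vox = np.round(pts).astype(int)
    vox = np.clip(vox, 0, np.asarray(shape) - 1)
    # drop consecutive duplicates but keep path order
    keep = np.r_[True, np.any(np.diff(vox, axis=0) != 0, axis=1)]
    return vox[keep]


def _skeleton_from_path(path_vox: np.ndarray) -> Skeleton:
    parents = np.r_[-1, np.arange(len(path_vox) - 1)]
    return Skeleton(coords=path_vox.astype(float), parents=parents, soma_index=0)


def _truth_ball(shape, center, radius) -> list[tuple[int, int, int]]:
    """Voxels of the noiseless blob at or above half its peak."""
    r_t = _HALF_PEAK * radius
    lo = np.maximum(np.floor(np.asarray(center) - r_t).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + r_t).astype(int), np.asarray(shape) - 1)
    zz, yy, xx = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    sel = d2 <= r_t**2 + 1e-9
    return list(zip(zz[sel].tolist(), yy[sel].tolist(), xx[sel].tolist()))


def _add_blob(field_arr, center, radius, amplitude) -> None:
    sigma = radius / 2.0
    extent = int(np.ceil(3 * sigma)) + 1
    shape = field_arr.shape
    lo = np.maximum(np.asarray(center) - extent, 0)
    hi = np.minimum(np.asarray(center) + extent, np.asarray(shape) - 1)
    zz, yy, xx = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    field_arr[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += (
        amplitude * np.exp(-d2 / (2.0 * sigma**2))
    )


def generate_sample(spec: SyntheticSpec, image_id: str = "synthetic") -> SyntheticSample:
    """Render one synthetic two-channel stack with ground truth.

    Deterministic for a fixed ``spec.seed``.  Puncta centres are drawn from
    neurite voxels; under ``non_overlapping`` (default) centres are rejected
    until all half-peak supports are pairwise separated by more than a voxel
    diagonal, so the ground-truth label has exactly ``n_puncta`` connected
    components.  Raises :class:`PlacementError` if placement fails after
    bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    path_vox = _polyline_voxels(spec.neurite_paths, shape)
    skeleton = _skeleton_from_path(path_vox)

    on_path = np.zeros(shape, dtype=bool)
    on_path[tuple(path_vox.T)] = True
    dist_to_skel = ndimage.distance_transform_edt(~on_path)
    neurite_mask = dist_to_skel <= spec.neurite_radius

    amplitude = spec.puncta_peak_intensity - spec.background_level

    # ---- puncta placement on the neurite ------------------------------
    candidates = np.argwhere(neurite_mask)
    margin_arr = np.asarray(shape) - 1
    centers: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 300 * max(spec.n_puncta, 1)
    tries = 0
    while len(centers) < spec.n_puncta and tries < max_tries:
        tries += 1
        c = candidates[rng.integers(len(candidates))]
        r = float(rng.uniform(*spec.puncta_radius_range))
        r_t = _HALF_PEAK * r
        if np.any(c - r_t < 0) or np.any(c + r_t > margin_arr):
            continue
        if spec.non_overlapping:
            ok = True
            for c2, r2 in zip(centers, radii):
                min_sep = _HALF_PEAK * (r + r2) + 2.0  # keep supports 26-disconnected
                if np.linalg.norm(c - c2) < min_sep:
                    ok = False
                    break
            if not ok:
                continue
        centers.append(c.copy())
        radii.append(r)
    if len(centers) < spec.n_puncta:
        raise PlacementError(spec.n_puncta, len(centers))

    synapse_noiseless = np.zeros(shape, dtype=float)
    synapse_truth = np.zeros(shape, dtype=bool)
    puncta_truth = []
    for c, r in zip(centers, radii):
        _add_blob(synapse_noiseless, c, r, amplitude)
        for v in _truth_ball(shape, c, r):
            synapse_truth[v] = True
        puncta_truth.append((tuple(int(x) for x in c), r))

    # ---- clutter: autofluorescence-like blobs off the neurite ----------
    placed_clutter = 0
    tries = 0
    far_enough = dist_to_skel > (spec.neurite_radius + 2.0 * spec.neurite_radius)
    far_candidates = np.argwhere(far_enough)
    while placed_clutter < spec.n_clutter and tries < 300 * max(spec.n_clutter, 1):
        tries += 1
        c = far_candidates[rng.integers(len(far_candidates))]
        r = float(rng.uniform(*spec.puncta_radius_range))
        if np.any(c - r < 0) or np.any(c + r > margin_arr):
            continue
        _add_blob(synapse_noiseless, c, r, amplitude)
        placed_clutter += 1

    # ---- channels ------------------------------------------------------
    cyto = np.zeros(shape, dtype=float)
    # soft-edged tube: full intensity inside the radius, 1-voxel fall-off
    edge = np.clip(spec.neurite_radius + 1.0 - dist_to_skel, 0.0, 1.0)
    cyto += spec.cytoplasmic_peak * edge

    syn_img = spec.background_level + synapse_noiseless + rng.normal(0, spec.noise_sd, shape)
    cyto_img = spec.background_level + cyto + rng.normal(0, spec.noise_sd, shape)

    image = VolumetricImage(
        channels={
            SYNAPSE_CHANNEL: np.clip(syn_img, 0, None).astype(np.float32),
            CYTOPLASMIC_CHANNEL: np.clip(cyto_img, 0, None).astype(np.float32),
        },
        spacing=(1.0, 1.0, 1.0),
        provenance=f"synthetic:seed={spec.seed}",
    )
    return SyntheticSample(
        image=image,
        neurite_truth=LabelVolume(neurite_mask, kind="neurite_mask"),
        synapse_truth=LabelVolume(synapse_truth, kind="synapse_truth"),
        skeleton_truth=skeleton,
        puncta_truth=puncta_truth,
        spec=spec,
        image_id=image_id,
    )


def generate_dataset(spec: SyntheticSpec, n_images: int) -> list[SyntheticSample]:
    """Generate ``n_images`` independent samples with seeds derived from ``spec.seed``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(n_images) % (2**31)
    samples = []
    for i, child in enumerate(child_seeds):
        sub = dataclasses.replace(spec, seed=int(child))
        samples.append(generate_sample(sub, image_id=f"synthetic_{spec.seed}_{i}"))
    return samples


def save_sample(sample: SyntheticSample, out_dir: str | Path) -> None:
    """Write a sample to disk: TIFF channels, TIFF labels, SWC skeleton,
    ground-truth puncta CSV and the generating spec as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = sample.image
    quantized = {
        name: np.clip(np.round(ch), 0, 65535).astype(np.uint16)
        for name, ch in img.channels.items()
    }
    write_stack(
        VolumetricImage(quantized, img.spacing, img.provenance),
        {name: out / f"{name}.tif" for name in quantized},
    )
    write_label(sample.neurite_truth, out / "neurite_truth.tif")
    write_label(sample.synapse_truth, out / "synapse_truth.tif")
    write_swc(sample.skeleton_truth.to_swc_rows(), out / "skeleton.swc")
    with open(out / "puncta_truth.csv", "w") as fh:
        fh.write("z,y,x,radius\n")
        for (z, y, x), r in sample.puncta_truth:
            fh.write(f"{z},{y},{x},{r:.3f}\n")
    with open(out / "spec.json", "w") as fh:
        json.dump(dataclasses.asdict(sample.spec), fh, indent=2, default=list)


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a spec back from its JSON form; spec + seed fully determine a dataset."""
    with open(path) as fh:
        raw = json.load(fh)
    raw["shape"] = tuple(raw["shape"])
    raw["puncta_radius_range"] = tuple(raw["puncta_radius_range"])
    raw["neurite_paths"] = tuple(
        tuple(tuple(pt) for pt in path) for path in raw["neurite_paths"]
    )
    return SyntheticSpec(**raw)
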