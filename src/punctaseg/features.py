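"""Per-pixel local image features for the synapse pixel classifier.

Each pixel is described by a bank of local filter responses computed on the
synapse channel and, when present, the cytoplasmic channel: the raw value,
in-plane Sobel gradient magnitude, difference of Gaussians at two scale
pairs, Laplacian of Gaussian at two scales, local mean and standard
deviation in a 3×3×3 window, and grayscale erosion with a 3×3×3
structuring element — nine features per channel.  In-plane filters (Sobel,
DoG, LoG) are applied slice-by-slice; the windowed statistics and erosion
are fully 3D.  Filter scales default to {1, 2, 4} voxels, bracketing the
1–3-voxel radius of small puncta.  Boundaries are handled by reflection.

Features are standardised (zero mean, unit variance per feature) with a
scaler fitted on the training pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from sklearn.preprocessing import StandardScaler

from .io import CYTOPLASMIC_CHANNEL, SYNAPSE_CHANNEL, VolumetricImage

__all__ = ["FeatureBank", "FeatureScaler", "compute_feature_volumes", "compute_features"]

#: default bank: 9 features per channel
DEFAULT_FEATURES = (
    "value",
    "sobel_magnitude",
    "dog_1_2",
    "dog_2_4",
    "log_1",
    "log_2",
    "local_mean_3",
    "local_std_3",
    "erosion_3",
)


@dataclass(frozen=True)
class FeatureBank:
    """An ordered list of filter names applied to an ordered list of channels.

    The feature vector of a pixel is the concatenation, channel-major, of
    every filter response at that pixel; with the default bank this is 9
    features for a synapse-only image and 18 when a cytoplasmic channel is
    present.
    """

    features: tuple[str, ...] = DEFAULT_FEATURES
    scales: tuple[float, ...] = (1.0, 2.0, 4.0)

    def channel_names(self, image: VolumetricImage) -> list[str]:
        names = [SYNAPSE_CHANNEL]
        if image.cytoplasmic is not None:
            names.append(CYTOPLASMIC_CHANNEL)
        return names

    def vector_length(self, image: VolumetricImage) -> int:
        return len(self.features) * len(self.channel_names(image))


@lru_cache(maxsize=None)
def _log_dc_gain(sigma: float) -> float:
    """Residual response of the truncated LoG kernel to a constant field."""
    size = 2 * int(4 * sigma + 1) + 9
    flat = np.ones((size, size))
    return float(ndimage.gaussian_laplace(flat, sigma=sigma, mode="reflect")[size // 2, size // 2])


def _slicewise(func, volume: np.ndarray) -> np.ndarray:
    out = np.empty_like(volume, dtype=float)
    for z in range(volume.shape[0]):
        out[z] = func(volume[z])
    return out


def _compute_one(volume: np.ndarray, name: str) -> np.ndarray:
    v = volume.astype(float)
    if name == "value":
        return v
    if name == "sobel_magnitude":
        def mag(sl):
            gy = ndimage.sobel(sl, axis=0, mode="reflect")
            gx = ndimage.sobel(sl, axis=1, mode="reflect")
            return np.hypot(gy, gx)
        return _slicewise(mag, v)
    if name == "sobel_dy":
        return _slicewise(lambda sl: ndimage.sobel(sl, axis=0, mode="reflect"), v)
    if name == "sobel_dx":
        return _slicewise(lambda sl: ndimage.sobel(sl, axis=1, mode="reflect"), v)
    if name.startswith("dog_"):
        _, s1, s2 = name.split("_")
        lo = ndimage.gaussian_filter(v, sigma=(0, float(s1), float(s1)), mode="reflect")
        hi = ndimage.gaussian_filter(v, sigma=(0, float(s2), float(s2)), mode="reflect")
        return lo - hi
    if name.startswith("log_"):
        s = float(name.split("_")[1])
        dc = _log_dc_gain(s)  # make the kernel exactly zero-sum
        return _slicewise(
            lambda sl: ndimage.gaussian_laplace(sl, sigma=s, mode="reflect") - dc * sl, v
        )
    if name.startswith("local_mean_"):
        size = int(name.split("_")[2])
        return ndimage.uniform_filter(v, size=size, mode="reflect")
    if name.startswith("local_std_"):
        size = int(name.split("_")[2])
        m = ndimage.uniform_filter(v, size=size, mode="reflect")
        m2 = ndimage.uniform_filter(v * v, size=size, mode="reflect")
        return np.sqrt(np.clip(m2 - m * m, 0.0, None))
    if name.startswith("erosion_"):
        size = int(name.split("_")[1])
        return ndimage.grey_erosion(v, size=(size, size, size), mode="reflect")
    raise KeyError(f"unknown feature {name!r}")


def compute_feature_volumes(
    image: VolumetricImage, bank: FeatureBank | None = None
) -> np.ndarray:
    """Compute every filter response over the full volume.

    Returns an ``(n_features, Z, Y, X)`` array, channel-major in the bank's
    fixed order.  Computing whole volumes once and indexing into them is far
    cheaper than per-pixel evaluation for the image sizes this pipeline
    targets.
    """
    bank = bank or FeatureBank()
    stacks = []
    for ch in bank.channel_names(image):
        vol = image.channels[ch]
        for name in bank.features:
            stacks.append(_compute_one(vol, name))
    return np.stack(stacks)


def compute_features(
    image: VolumetricImage,
    pixels: np.ndarray,
    bank: FeatureBank | None = None,
    volumes: np.ndarray | None = None,
) -> np.ndarray:
    """Feature matrix ``(n_pixels, n_features)`` at (z, y, x) coordinates.

    ``volumes`` may pass precomputed :func:`compute_feature_volumes` output
    to amortise filtering across calls.  Out-of-bounds coordinates raise.
    """
    bank = bank or FeatureBank()
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    shape = np.asarray(image.shape)
    if np.any(pixels < 0) or np.any(pixels >= shape[None, :]):
        raise IndexError("pixel coordinate out of bounds")
    if volumes is None:
        volumes = compute_feature_volumes(image, bank)
    return volumes[:, pixels[:, 0], pixels[:, 1], pixels[:, 2]].T.copy()


@dataclass
class FeatureScaler:
    """Standard scaler (zero mean, unit variance per feature) for pixel features."""

    _scaler: StandardScaler = field(default_factory=StandardScaler)
    fitted: bool = False

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        self._scaler.fit(X)
        self.fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return self._scaler.transform(X)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self.fitted = True
        return self._scaler.fit_transform(X)

    @property
    def mean_(self) -> np.ndarray:
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        return self._scaler.scale_
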