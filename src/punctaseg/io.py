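"""Reading and writing the pipeline's on-disk artifacts.

Images and label volumes travel as grayscale multi-page TIFF, one file per
channel, axis order (Z, Y, X).  Labels are uint8 0/255 on disk; any nonzero
voxel reads back as true, so masks drawn with external annotation tools
survive a round trip.  Quantified puncta and per-image summaries are written
as UTF-8 CSV with a fixed schema; skeletons use the SWC interchange format.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: channel names with a defined meaning downstream
SYNAPSE_CHANNEL = "synapse"
CYTOPLASMIC_CHANNEL = "cytoplasmic"

PUNCTA_CSV_COLUMNS = [
    "image_id",
    "punctum_id",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "voxel_count",
    "volume_um3",
    "mean_intensity",
    "max_intensity",
    "total_intensity",
    "skeleton_position_norm",
]

SUMMARY_CSV_COLUMNS = [
    "image_id",
    "puncta_count",
    "total_volume",
    "mean_volume",
    "count_density",
    "volume_density",
    "domain_length",
]


@dataclass
class VolumetricImage:
    """A 3D intensity stack with named channels and physical voxel spacing.

    Parameters
    ----------
    channels:
        Mapping from channel name to a ``(Z, Y, X)`` array.  The ``synapse``
        channel is required by every downstream stage; ``cytoplasmic`` is
        optional and enables neurite masking.
    spacing:
        Physical voxel size in micrometres per axis, ``(z, y, x)``.
    provenance:
        Free-form origin note (source path or generator seed).
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VolumetricImage needs at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"channels must be 3D (Z,Y,X), got {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def synapse(self) -> np.ndarray:
        return self.channels[SYNAPSE_CHANNEL]

    @property
    def cytoplasmic(self) -> np.ndarray | None:
        return self.channels.get(CYTOPLASMIC_CHANNEL)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class LabelVolume:
    """A boolean voxel mask: neurite mask, synapse ground truth or prediction."""

    data: np.ndarray
    kind: str = "synapse_prediction"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if self.data.dtype != bool:
            self.data = self.data != 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def read_stack(
    paths: Mapping[str, str | Path] | str | Path,
    spacing: tuple[float, float, float] | None = None,
) -> VolumetricImage:
    """Read one TIFF stack per channel into a :class:`VolumetricImage`.

    ``paths`` is either a mapping ``{channel_name: tiff_path}`` or a single
    path (read as the synapse channel).  All channels must agree in shape.
    If no spacing is given and the files carry none, isotropic 1 µm is
    assumed with a logged warning.
    """
    if isinstance(paths, (str, Path)):
        paths = {SYNAPSE_CHANNEL: paths}
    channels: dict[str, np.ndarray] = {}
    for name, p in paths.items():
        arr = tifffile.imread(str(p))
        if arr.ndim == 2:  # single-slice stack
            arr = arr[None]
        channels[name] = arr
    shapes = {n: c.shape for n, c in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel shapes disagree: {shapes}")
    if spacing is None:
        logger.warning(
            "no voxel spacing supplied; assuming isotropic 1 um "
            "(densities will be per voxel-unit)"
        )
        spacing = (1.0, 1.0, 1.0)
    prov = ";".join(str(p) for p in paths.values())
    return VolumetricImage(channels=channels, spacing=spacing, provenance=prov)


def write_stack(image: VolumetricImage, paths: Mapping[str, str | Path]) -> None:
    """Write each requested channel as a multi-page grayscale TIFF."""
    for name, p in paths.items():
        Path(p).parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(p), image.channels[name], photometric="minisblack")


def read_label(path: str | Path, kind: str = "synapse_prediction") -> LabelVolume:
    """Read a uint8 TIFF as a boolean mask; any nonzero voxel is true."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelVolume(data=arr != 0, kind=kind)


def write_label(label: LabelVolume, path: str | Path) -> None:
    """Write a boolean mask as uint8 0/255 TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), label.data.astype(np.uint8) * 255, photometric="minisblack")


def write_puncta_csv(puncta_set, path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write one row per punctum, plus an optional per-image summary CSV.

    The summary row (count, total/mean volume, densities over the synapse
    domain, domain length) is recomputed from the punctum rows by
    :meth:`punctaseg.quantify.PunctaSet.summarize`, so the two files are
    consistent by construction.  An empty set yields a header-only puncta
    file and an all-zero summary row.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PUNCTA_CSV_COLUMNS)
        for p in puncta_set.puncta:
            pos = "" if p.position_norm is None else f"{p.position_norm:.6f}"
            writer.writerow(
                [
                    puncta_set.image_id,
                    p.id,
                    f"{p.centroid[0]:.3f}",
                    f"{p.centroid[1]:.3f}",
                    f"{p.centroid[2]:.3f}",
                    p.voxel_count,
                    f"{p.volume_um3:.6f}",
                    f"{p.mean_intensity:.4f}",
                    f"{p.max_intensity:.4f}",
                    f"{p.total_intensity:.4f}",
                    pos,
                ]
            )
    if summary_path is not None:
        write_summary_csv([puncta_set.summarize()], summary_path)


def write_summary_csv(summaries: Iterable, path: str | Path) -> None:
    """Write per-image summary records (one row per image)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def fmt(v):
        if v is None:
            return "nan"
        return f"{v:.6f}" if isinstance(v, float) else v

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_CSV_COLUMNS)
        for s in summaries:
            writer.writerow(
                [
                    s.image_id,
                    s.puncta_count,
                    fmt(s.total_volume),
                    fmt(s.mean_volume),
                    fmt(s.count_density),
                    fmt(s.volume_density),
                    fmt(s.domain_length),
                ]
            )


def write_profile_csv(profile, path: str | Path) -> None:
    """Write a distribution profile as (bin_left, bin_right, density) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_left", "bin_right", "density"])
        for left, right, dens in zip(
            profile.bin_edges[:-1], profile.bin_edges[1:], profile.density
        ):
            writer.writerow([f"{left:.6f}", f"{right:.6f}", f"{dens:.8f}"])


def write_swc(nodes: Sequence[tuple], path: str | Path) -> None:
    """Write skeleton nodes as SWC.

    ``nodes`` holds ``(id, type, x, y, z, radius, parent_id)`` tuples in SWC
    column order (parent -1 for the root).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid, ntype, x, y, z, radius, parent in nodes:
            fh.write(f"{nid} {ntype} {x:.3f} {y:.3f} {z:.3f} {radius:.3f} {parent}\n")


def make_overlay(image: VolumetricImage, prediction: LabelVolume) -> np.ndarray:
    """Burn prediction outlines into the raw synapse channel for review.

    Returns a uint8 stack where voxels on the boundary of a predicted
    punctum are set to full intensity; scanning these overlays is the quick
    way to spot systematically missed or spurious regions.
    """
    from scipy import ndimage

    raw = image.synapse.astype(float)
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo) * 220.0
    overlay = scaled.astype(np.uint8)
    eroded = ndimage.binary_erosion(prediction.data)
    boundary = prediction.data & ~eroded
    overlay[boundary] = 255
    return overlay
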