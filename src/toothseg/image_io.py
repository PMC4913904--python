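"""Volumetric image I/O and intensity utilities.

All volumes are indexed ``(z, y, x)`` (slice-stack native order, 0-based).
Voxel spacing is ``(dz, dy, dx)`` in millimetres; when a file carries no
geometry metadata the spacing defaults to 1.00 mm isotropic, the acquisition
geometry of the micro-CT datasets this package targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile
import yaml

__all__ = [
    "Volume3D",
    "LabelVolume",
    "DEFAULT_LABEL_MAP",
    "DEFAULT_DISPLAY_GRAY",
    "read_volume",
    "write_volume",
    "normalize_intensity",
    "write_labels",
    "read_labels",
    "load_config",
    "save_config",
]

DEFAULT_SPACING = (1.0, 1.0, 1.0)

#: Integer classes of the classification output.
DEFAULT_LABEL_MAP = {0: "background", 1: "pulp", 2: "dentine", 3: "enamel"}

#: 8-bit export grays: background black, pulp dark grey, dentine grey,
#: enamel white (bright -> dense tissue).
DEFAULT_DISPLAY_GRAY = {0: 0, 1: 96, 2: 160, 3: 255}


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities, arbitrary units or normalized [0, 1].
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm; all components > 0.
    origin : tuple of int
        Voxel offset of this volume within its parent (used by ROI crops).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, new scalar grid (shape must match)."""
        if np.shape(data) != self.data.shape:
            raise ValueError("derived volume must keep the parent shape")
        return replace(self, data=np.asarray(data))


@dataclass
class LabelVolume:
    """Integer class grid with a label dictionary and export grays."""

    data: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    display_gray: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_DISPLAY_GRAY))
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D labels, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label grid must be integer typed")
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.label_map)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _read_png_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in {".png", ".bmp", ".tif", ".tiff"}
    )
    if not files:
        raise IOError(f"no image slices found in {path}")
    slices = [np.asarray(iio.imread(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise ValueError("slices must be single-channel 2D images")
    return np.stack(slices, axis=0)


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores (x, y, z); flip to stack order (z, y, x).
    data = np.transpose(arr, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        spacing = DEFAULT_SPACING
    return data, spacing


def read_volume(
    path: str | Path,
    format: str | None = None,
    *,
    shape: tuple[int, int, int] | None = None,
    dtype: str = "uint8",
) -> Volume3D:
    """Read a 3D grayscale volume.

    ``format`` is one of ``tiff_stack``, ``nifti``, ``png_dir``, ``raw``;
    when omitted it is inferred from the path. Raw files need an explicit
    ``shape`` (and ``dtype``). Slices of a directory are stacked in
    lexicographic filename order. Spacing is taken from file metadata when
    present, else defaults to 1 mm isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "png_dir"
        elif path.suffix.lower() in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
            format = "nifti"
        elif path.suffix.lower() in {".tif", ".tiff"}:
            format = "tiff_stack"
        elif path.suffix.lower() == ".raw":
            format = "raw"
        else:
            raise ValueError(f"cannot infer format of {path}")

    spacing = DEFAULT_SPACING
    if format == "tiff_stack":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]  # single-slice file -> degenerate stack
    elif format == "nifti":
        data, spacing = _read_nifti(path)
    elif format == "png_dir":
        data = _read_png_dir(path)
    elif format == "raw":
        if shape is None:
            raise ValueError("raw format requires an explicit shape")
        data = np.fromfile(path, dtype=np.dtype(dtype))
        if data.size != int(np.prod(shape)):
            raise ValueError(f"raw file size does not match shape {shape}")
        data = data.reshape(shape)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Volume3D(np.asarray(data, dtype=np.float64), spacing=spacing)


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as multi-page TIFF (float32) or NIfTI."""
    path = Path(path)
    if format is None:
        format = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "tiff_stack"
    if format == "tiff_stack":
        tifffile.imwrite(str(path), vol.data.astype(np.float32),
                         photometric="minisblack")
    elif format == "nifti":
        dz, dy, dx = vol.spacing
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.transpose(vol.data, (2, 1, 0)), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def normalize_intensity(vol: Volume3D) -> Volume3D:
    """Linearly rescale intensities to [0, 1]; constant volumes map to 0.

    Idempotent: applying it twice gives the same grid.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return vol.with_data(np.zeros_like(data))
    return vol.with_data((data - lo) / (hi - lo))


def write_labels(lab: LabelVolume, path: str | Path, format: str = "tiff_stack") -> Path:
    """Export a label volume as an 8-bit gray stack using ``display_gray``.

    Every label present must have a display gray; the mapping must be
    invertible so that :func:`read_labels` round-trips the integer grid.
    """
    present = np.unique(lab.data)
    missing = [int(v) for v in present if int(v) not in lab.display_gray]
    if missing:
        raise ValueError(f"no display gray for labels {missing}")
    grays = lab.display_gray
    if len(set(grays.values())) != len(grays):
        raise ValueError("display grays must be distinct for round-tripping")
    lut = np.zeros(max(grays) + 1, dtype=np.uint8)
    for k, g in grays.items():
        lut[k] = g
    out = lut[lab.data]
    path = Path(path)
    if format == "tiff_stack":
        tifffile.imwrite(str(path), out, photometric="minisblack")
    elif format == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        for z in range(out.shape[0]):
            iio.imwrite(path / f"slice_{z:04d}.png", out[z])
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_labels(
    path: str | Path,
    label_map: dict[int, str] | None = None,
    display_gray: dict[int, int] | None = None,
    format: str | None = None,
) -> LabelVolume:
    """Read an 8-bit gray stack back into integer classes (inverse of export)."""
    label_map = dict(label_map or DEFAULT_LABEL_MAP)
    display_gray = dict(display_gray or DEFAULT_DISPLAY_GRAY)
    vol = read_volume(path, format=format)
    gray = vol.data.astype(np.int64)
    inverse = {g: k for k, g in display_gray.items()}
    data = np.zeros_like(gray)
    seen = np.zeros(gray.shape, dtype=bool)
    for g, k in inverse.items():
        hit = gray == g
        data[hit] = k
        seen |= hit
    if not seen.all():
        bad = np.unique(gray[~seen])
        raise ValueError(f"gray values {bad.tolist()} not in display map")
    return LabelVolume(data, label_map=label_map, display_gray=display_gray,
                       spacing=vol.spacing)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
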