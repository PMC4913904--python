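"""Synthetic single-tooth micro-CT phantom with exact ground-truth labels.

The phantom emulates a single mandibular molar scanned on a bracket: nested
structures in three intensity tiers (enamel bright, dentine mid, pulp
low-mid) inside a dark background, plus a bracket rod of tooth-like
intensity touching the tooth base — the configuration that makes the
segmentation problem hard in the real scans.  Geometry:

* tooth = ellipsoid (crown up, root down along +z);
* enamel = the outer shell of the upper crown (above the neck plane and
  outside a scaled copy of the tooth ellipsoid);
* pulp = pulp-chamber ellipsoid plus a root-canal cylinder running toward
  the root apex;
* dentine = the remaining tooth interior;
* bracket = a vertical cylinder from just inside the root apex down to the
  bottom of the grid (background label: it is not tooth tissue).

Additive Gaussian noise (clipped to [0, 1]) is applied to the intensity
volume only; labels are the exact pre-noise geometry.  Everything is
deterministic given ``rng_seed``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import (DEFAULT_DISPLAY_GRAY, DEFAULT_LABEL_MAP, LabelVolume,
                       Volume3D)

__all__ = ["PhantomSpec", "generate", "save_truth_report"]

BACKGROUND, PULP, DENTINE, ENAMEL = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Phantom geometry, intensity tiers and noise.

    Defaults use a 128^3 grid at 1 mm isotropic spacing with tier means
    background 0.05 < pulp 0.35 < dentine 0.65 < enamel 0.95, a bracket at
    0.70 (between dentine and enamel, so it genuinely challenges the
    segmentation), and noise sd 0.02.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mean_background: float = 0.05
    mean_pulp: float = 0.35
    mean_dentine: float = 0.65
    mean_enamel: float = 0.95
    mean_bracket: float = 0.70
    noise_sd: float = 0.02
    bracket: bool = True
    # geometry (voxel units, scaled to the default 128 grid)
    tooth_center: tuple[float, float, float] = (60.0, 64.0, 64.0)
    tooth_semiaxes: tuple[float, float, float] = (44.0, 30.0, 30.0)
    enamel_inner_scale: float = 0.78
    neck_z: float = 60.0
    pulp_center: tuple[float, float, float] = (58.0, 64.0, 64.0)
    pulp_semiaxes: tuple[float, float, float] = (14.0, 9.0, 9.0)
    canal_radius: float = 4.0
    canal_end_z: float = 95.0
    bracket_radius: float = 5.0
    bracket_start_z: float = 101.0
    rng_seed: int = 20160620

    def __post_init__(self) -> None:
        if not (self.mean_background < self.mean_pulp < self.mean_dentine
                < self.mean_enamel):
            raise ValueError("tier means must satisfy background < pulp < "
                             "dentine < enamel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.enamel_inner_scale < 1):
            raise ValueError("enamel_inner_scale must be in (0, 1)")
        if any(p >= t for p, t in zip(self.pulp_semiaxes, self.tooth_semiaxes)):
            raise ValueError("pulp ellipsoid must nest inside the tooth")


def _ellipsoid(grid: tuple[np.ndarray, np.ndarray, np.ndarray],
               center: tuple[float, float, float],
               semiaxes: tuple[float, float, float],
               scale: float = 1.0) -> np.ndarray:
    zz, yy, xx = grid
    cz, cy, cx = center
    az, ay, ax = (s * scale for s in semiaxes)
    return (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0


def generate(spec: PhantomSpec | None = None) -> tuple[Volume3D, LabelVolume]:
    """Build the phantom; returns the noisy intensity volume and exact labels."""
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.shape
    grid = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                       indexing="ij", sparse=True)
    zz, yy, xx = grid

    tooth = _ellipsoid(grid, spec.tooth_center, spec.tooth_semiaxes)
    inner = _ellipsoid(grid, spec.tooth_center, spec.tooth_semiaxes,
                       scale=spec.enamel_inner_scale)
    if not tooth.any():
        raise ValueError("tooth ellipsoid lies outside the grid")

    enamel = tooth & ~inner & (zz < spec.neck_z)
    chamber = _ellipsoid(grid, spec.pulp_center, spec.pulp_semiaxes)
    if not (chamber & ~tooth).sum() == 0:
        raise ValueError("pulp chamber must nest inside the tooth")
    cz, cy, cx = spec.pulp_center
    canal = (((yy - cy) ** 2 + (xx - cx) ** 2) <= spec.canal_radius ** 2) \
        & (zz >= cz) & (zz <= spec.canal_end_z)
    pulp = (chamber | canal) & tooth & ~enamel
    dentine = tooth & ~enamel & ~pulp

    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[pulp] = PULP
    labels[dentine] = DENTINE
    labels[enamel] = ENAMEL

    intensity = np.full(spec.shape, spec.mean_background, dtype=np.float64)
    intensity[pulp] = spec.mean_pulp
    intensity[dentine] = spec.mean_dentine
    intensity[enamel] = spec.mean_enamel
    if spec.bracket:
        _, by, bx = spec.tooth_center
        rod = (((yy - by) ** 2 + (xx - bx) ** 2) <= spec.bracket_radius ** 2) \
            & (zz >= spec.bracket_start_z)
        intensity[rod & ~tooth] = spec.mean_bracket

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        intensity = np.clip(intensity, 0.0, 1.0)

    vol = Volume3D(intensity, spacing=spec.spacing)
    lab = LabelVolume(labels, label_map=dict(DEFAULT_LABEL_MAP),
                      display_gray=dict(DEFAULT_DISPLAY_GRAY),
                      spacing=spec.spacing)
    return vol, lab


def save_truth_report(lab: LabelVolume, path: str | Path) -> Path:
    """Write per-structure true voxel counts and volumes (mm^3) to CSV."""
    dz, dy, dx = lab.spacing
    voxel = dz * dy * dx
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure", "label", "voxels", "volume_mm3"])
        for label, name in sorted(lab.label_map.items()):
            count = int(np.count_nonzero(lab.data == label))
            writer.writerow([name, label, count, count * voxel])
    return path
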