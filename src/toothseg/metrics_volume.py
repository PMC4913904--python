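"""Quasi-Monte Carlo volume estimation and evaluation statistics.

Structure volumes are estimated per slice with Halton low-discrepancy
points: N points are scattered over the bounding box of the target region
in each slice, the slice area is S_i = (m/N) * S_box with m the number of
points landing on region pixels, and the volume is the sum of slice areas
times the slice thickness.  Being deterministic, the estimator converges to
the voxel-count volume as N grows (O(log N / N) discrepancy) without a
random seed.

Agreement between computed and ground-truth volumes is summarized by the
signed relative error E = (computed - true) / true, the mean absolute
deviation (MAD) in mm^3, and a correlation coefficient with an
absolute-value numerator (so perfectly anti-correlated vectors also score
1).  Voxel-overlap agreement between an automatic classification A and the
reference D uses the similarity index S = 2|A n D| / (|A| + |D|) (Dice;
S > 0.7 conventionally indicates strong agreement), the sensitivity
SENS = |A n D| / |D| and the specificity SPEC = |A n D| / |A|; high SENS
with low SPEC flags over-segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import LabelVolume

__all__ = [
    "HaltonConfig",
    "VolumePair",
    "MetricsReport",
    "halton",
    "halton_points",
    "slice_area",
    "estimate_volume",
    "voxel_volume",
    "relative_error",
    "mad",
    "corrco",
    "overlap_indexes",
]


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    return all(n % d for d in range(2, int(n ** 0.5) + 1))


@dataclass
class HaltonConfig:
    """Points per slice and the (coprime prime) radical-inverse bases."""

    n_points: int = 100_000
    bases: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        b1, b2 = self.bases
        if not (_is_prime(b1) and _is_prime(b2)) or b1 == b2:
            raise ValueError("bases must be two distinct primes")


@dataclass
class VolumePair:
    """A computed volume against its ground truth (mm^3)."""

    computed: float
    true_: float
    structure: str = ""
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.computed < 0 or self.true_ < 0:
            raise ValueError("volumes must be >= 0")


@dataclass
class MetricsReport:
    """Volume agreement and per-structure overlap statistics."""

    pairs: list[VolumePair] = field(default_factory=list)
    relative_errors: list[float] = field(default_factory=list)
    mad: float | None = None
    corrco: float | None = None
    overlap: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pairs": [{"structure": p.structure, "case_id": p.case_id,
                       "computed": p.computed, "true": p.true_}
                      for p in self.pairs],
            "relative_errors": self.relative_errors,
            "mad": self.mad,
            "corrco": self.corrco,
            "overlap": {k: {"S": v[0], "SENS": v[1], "SPEC": v[2]}
                        for k, v in self.overlap.items()},
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def halton(index: int, base: int) -> float:
    """Radical inverse of ``index >= 1`` in a prime base.

    Digits of the index in the base, mirrored about the radix point:
    base 2 gives 1/2, 1/4, 3/4, 1/8, 5/8, ...
    """
    if index < 1:
        raise ValueError("index must be >= 1")
    result, f = 0.0, 1.0
    i = index
    while i > 0:
        f /= base
        result += f * (i % base)
        i //= base
    return result


def halton_points(n: int, bases: tuple[int, int] = (2, 3),
                  start: int = 1) -> np.ndarray:
    """``n`` 2D Halton points in [0, 1)^2 (vectorized radical inverse)."""
    idx = np.arange(start, start + n, dtype=np.int64)
    pts = np.empty((n, 2), dtype=np.float64)
    for d, base in enumerate(bases):
        i = idx.copy()
        out = np.zeros(n, dtype=np.float64)
        f = 1.0
        while i.max() > 0:
            f /= base
            out += f * (i % base)
            i //= base
        pts[:, d] = out
    return pts


def slice_area(region: np.ndarray, cfg: HaltonConfig | None = None,
               pixel_area: float = 1.0) -> float:
    """Halton-point area (mm^2) of a 2D binary region.

    N points are scattered over the region's bounding box; the area is the
    hit fraction times the box area.  An empty region has area 0; a region
    filling its box is measured exactly for any N.
    """
    cfg = cfg or HaltonConfig()
    region = np.asarray(region).astype(bool)
    if region.ndim != 2:
        raise ValueError("region must be a 2D mask")
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    if rows.size == 0:
        return 0.0
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    box = region[r0:r1, c0:c1]
    pts = halton_points(cfg.n_points, cfg.bases)
    ri = np.minimum((pts[:, 0] * box.shape[0]).astype(np.int64), box.shape[0] - 1)
    ci = np.minimum((pts[:, 1] * box.shape[1]).astype(np.int64), box.shape[1] - 1)
    m = int(box[ri, ci].sum())
    s_box = box.shape[0] * box.shape[1] * pixel_area
    return (m / cfg.n_points) * s_box


def estimate_volume(labels: LabelVolume, label: int,
                    cfg: HaltonConfig | None = None,
                    spacing: tuple[float, float, float] | None = None) -> float:
    """Halton volume (mm^3) of one label: per-slice areas summed over the stack."""
    if label not in labels.label_map:
        raise ValueError(f"label {label} not in label map {labels.label_map}")
    cfg = cfg or HaltonConfig()
    dz, dy, dx = spacing or labels.spacing
    total = 0.0
    for z in range(labels.shape[0]):
        total += slice_area(labels.data[z] == label, cfg, pixel_area=dy * dx) * dz
    return total


def voxel_volume(labels: LabelVolume, label: int,
                 spacing: tuple[float, float, float] | None = None) -> float:
    """Exact voxel-count volume (mm^3); the oracle for the Halton estimator."""
    if label not in labels.label_map:
        raise ValueError(f"label {label} not in label map {labels.label_map}")
    dz, dy, dx = spacing or labels.spacing
    return float(np.count_nonzero(labels.data == label)) * dz * dy * dx


def relative_error(pair: VolumePair) -> float:
    """Signed relative error E = (computed - true) / true."""
    if pair.true_ <= 0:
        raise ValueError("true volume must be positive")
    return (pair.computed - pair.true_) / pair.true_


def mad(pairs: list[VolumePair]) -> float:
    """Mean absolute deviation |computed - true| over the pairs (mm^3)."""
    if not pairs:
        raise ValueError("need at least one volume pair")
    return float(np.mean([abs(p.computed - p.true_) for p in pairs]))


def corrco(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation coefficient in [0, 1] with absolute-value numerator.

    |sum (x - xbar)(y - ybar)| / sqrt(sum (x - xbar)^2 * sum (y - ybar)^2);
    1 for perfect (anti-)correlation.  Undefined for constant vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return abs(float(dx @ dy)) / np.sqrt(sxx * syy)


def overlap_indexes(A: np.ndarray, D: np.ndarray) -> tuple[float, float, float]:
    """Similarity index, sensitivity and specificity of masks A (automatic)
    vs D (reference).

    S = 2|A n D| / (|A| + |D|), SENS = |A n D| / |D|, SPEC = |A n D| / |A|;
    all equal 1 at total overlap.
    """
    A = np.asarray(A).astype(bool)
    D = np.asarray(D).astype(bool)
    if A.shape != D.shape:
        raise ValueError("masks must share a shape")
    a = int(A.sum())
    d = int(D.sum())
    if d == 0:
        raise ValueError("sensitivity undefined: reference mask is empty")
    if a == 0:
        raise ValueError("specificity undefined: automatic mask is empty")
    inter = int((A & D).sum())
    return 2 * inter / (a + d), inter / d, inter / a
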