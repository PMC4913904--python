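"""End-to-end framework: ROI crop -> 3D GFRLS -> morphological cleanup ->
grayscale masking -> enamel threshold -> PCNN interior classification ->
label composition.

The tooth is first segmented as a whole by the 3D level set; the binary
mask is cleaned morphologically (erosion-based speckle removal and a
largest-connected-component safeguard against bracket remnants); masking
the original intensities with it yields a grayscale tooth image; enamel is
split off by an intensity threshold (fixed or between-class-variance
"auto"); the remaining tooth interior is classified slice-by-slice with the
hierarchical PCNN into dentine vs pulp (the class with the higher mean
original intensity is dentine — dentine is the brighter tissue in
micro-CT); and the labels are composed into one partition (enamel wins over
PCNN labels, background where the mask is 0) in full-volume coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import gfrls3d, pcnn
from .image_io import (DEFAULT_DISPLAY_GRAY, DEFAULT_LABEL_MAP, LabelVolume,
                       Volume3D, normalize_intensity)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "extract_roi",
    "erode_mask",
    "clean_mask",
    "mask_to_gray",
    "extract_enamel",
    "run_pipeline",
]

BACKGROUND, PULP, DENTINE, ENAMEL = 0, 1, 2, 3


def _cross_se() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


@dataclass
class PipelineConfig:
    """End-to-end parameters.

    seed_point : a voxel inside the tooth; the ROI is the cube of half-width
        ``block_radius`` around it (clipped to the volume).
    erosion_iters : iterations of binary erosion used for speckle removal.
    reconstruct : when True (default) the erosion is followed by
        morphological reconstruction (opening-by-reconstruction): speckles
        that do not survive the erosion are removed while surviving
        structure keeps its original boundary, so structure volumes are not
        biased by the cleanup.  Set False for plain iterated erosion.
    keep_largest : retain only the largest 26-connected mask component
        (safeguard against residual bracket fragments).
    enamel_threshold : intensity in (0, 1), or "auto" for the maximal
        between-class-variance split of the nonzero tooth intensities.
    pcnn : PCNN parameters for the interior classification; ``pcnn.k = 2``
        resolves dentine vs pulp.
    """

    seed_point: tuple[int, int, int] | None = None
    block_radius: int = 64
    gfrls: gfrls3d.GFRLSParams = field(default_factory=gfrls3d.GFRLSParams)
    erosion_iters: int = 1
    erosion_se: np.ndarray = field(default_factory=_cross_se)
    reconstruct: bool = True
    keep_largest: bool = True
    enamel_threshold: float | str = 0.8
    pcnn: pcnn.PCNNParams = field(default_factory=lambda: pcnn.PCNNParams(k=2))

    def __post_init__(self) -> None:
        if self.block_radius < 1:
            raise ValueError("block_radius must be >= 1")
        if self.erosion_iters < 0:
            raise ValueError("erosion_iters must be >= 0")
        if isinstance(self.enamel_threshold, str):
            if self.enamel_threshold != "auto":
                raise ValueError("enamel_threshold must be a float or 'auto'")
        elif not (0 < self.enamel_threshold <= 1):
            raise ValueError("enamel_threshold must be in (0, 1]")


@dataclass
class PipelineReport:
    """Per-stage telemetry of one pipeline run."""

    roi_origin: tuple[int, int, int]
    roi_shape: tuple[int, int, int]
    gfrls_converged: bool
    gfrls_iterations: int
    enamel_threshold: float
    tooth_voxels: int
    voxels_per_class: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def extract_roi(vol: Volume3D, seed_point: tuple[int, int, int],
                block_radius: int) -> Volume3D:
    """Cube crop of half-width ``block_radius`` around the seed, clipped to
    the volume; the crop origin is recorded for paste-back."""
    shape = vol.shape
    for ax in range(3):
        if not (0 <= seed_point[ax] < shape[ax]):
            raise ValueError(f"seed {seed_point} outside volume of shape {shape}")
    lo = tuple(max(0, seed_point[ax] - block_radius) for ax in range(3))
    hi = tuple(min(shape[ax], seed_point[ax] + block_radius + 1) for ax in range(3))
    data = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return Volume3D(data, spacing=vol.spacing, origin=lo)


def erode_mask(mask: np.ndarray, se: np.ndarray | None = None,
               iterations: int = 1) -> np.ndarray:
    """Iterated binary erosion; the result is a subset of the input."""
    mask = np.asarray(mask).astype(bool)
    if iterations == 0:
        return mask.copy()
    se = _cross_se() if se is None else np.asarray(se).astype(bool)
    return ndimage.binary_erosion(mask, structure=se, iterations=iterations)


def clean_mask(mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Morphological cleanup of the segmentation mask.

    Erosion removes speckle noise; with ``reconstruct`` the surviving
    structure is grown back to its original extent (opening by
    reconstruction).  Optionally only the largest 26-connected component is
    kept.
    """
    mask = np.asarray(mask).astype(bool)
    cleaned = erode_mask(mask, config.erosion_se, config.erosion_iters)
    if config.reconstruct and config.erosion_iters > 0 and cleaned.any():
        # grow the eroded markers back inside the original mask
        cleaned = ndimage.binary_propagation(
            cleaned, structure=ndimage.generate_binary_structure(3, 3),
            mask=mask)
    if config.keep_largest and cleaned.any():
        labeled, n = ndimage.label(cleaned,
                                   structure=ndimage.generate_binary_structure(3, 3))
        if n > 1:
            sizes = ndimage.sum_labels(cleaned, labeled, index=np.arange(1, n + 1))
            cleaned = labeled == (1 + int(np.argmax(sizes)))
    return cleaned


def mask_to_gray(vol: Volume3D, mask: np.ndarray) -> Volume3D:
    """Grayscale tooth image: original intensities inside the mask, 0 outside."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError("mask and volume shapes differ")
    return vol.with_data(np.where(mask, vol.data, 0.0))


def extract_enamel(tooth_gray: Volume3D, threshold: float | str = "auto") -> np.ndarray:
    """Threshold the masked tooth image to the enamel (brightest) tier.

    ``threshold="auto"`` picks the maximal between-class-variance (Otsu)
    split of the nonzero intensities.  An empty tooth image yields an empty
    mask with a warning.
    """
    data = tooth_gray.data
    nonzero = data[data > 0]
    if nonzero.size == 0:
        warnings.warn("no tooth voxels: enamel mask is empty", RuntimeWarning,
                      stacklevel=2)
        return np.zeros(data.shape, dtype=bool)
    if threshold == "auto":
        threshold = float(threshold_otsu(nonzero))
    return (data >= threshold) & (data > 0)


def _classify_interior(tooth_gray: Volume3D, interior: np.ndarray,
                       params: pcnn.PCNNParams) -> np.ndarray:
    """Slice-wise PCNN classes of the non-enamel tooth interior."""
    classes = np.zeros(tooth_gray.shape, dtype=np.int64)
    for z in range(tooth_gray.shape[0]):
        sl = np.where(interior[z], tooth_gray.data[z], 0.0)
        if not interior[z].any():
            continue
        Y, _ = pcnn.run(sl, params)
        classes[z] = pcnn.labels_from_output(Y, params.k)
    return classes


def run_pipeline(vol: Volume3D, config: PipelineConfig | None = None
                 ) -> tuple[LabelVolume, PipelineReport]:
    """Execute the full framework on a volume; returns labels + report.

    The output is a partition of the input grid into background, pulp,
    dentine and enamel, in the input volume's coordinates.
    """
    config = config or PipelineConfig()
    vol = normalize_intensity(vol)
    seed = config.seed_point or tuple(s // 2 for s in vol.shape)
    roi = extract_roi(vol, seed, config.block_radius)
    report_warnings: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        seg = gfrls3d.segment(roi, config.gfrls, normalize=False)
        mask = clean_mask(seg.mask, config)
        tooth_gray = mask_to_gray(roi, mask)
        if not np.any(tooth_gray.data > 0):
            # constant/empty input: nothing resembling a tooth was found
            mask = np.zeros(roi.shape, dtype=bool)
            tooth_gray = mask_to_gray(roi, mask)
            warnings.warn("no tooth intensities inside the segmentation: "
                          "returning all-background labels", RuntimeWarning)
            enamel = np.zeros(roi.shape, dtype=bool)
        else:
            enamel = extract_enamel(tooth_gray, config.enamel_threshold)
        report_warnings.extend(str(w.message) for w in caught)
    if not seg.converged:
        report_warnings.append("GFRLS segmentation did not converge")

    if isinstance(config.enamel_threshold, str):
        nonzero = tooth_gray.data[tooth_gray.data > 0]
        eff_threshold = float(threshold_otsu(nonzero)) if nonzero.size else float("nan")
    else:
        eff_threshold = float(config.enamel_threshold)

    interior = mask & ~enamel
    classes = _classify_interior(tooth_gray, interior, config.pcnn)

    roi_labels = np.zeros(roi.shape, dtype=np.int64)
    present = [c for c in np.unique(classes[interior]) if interior.any()] \
        if interior.any() else []
    if present:
        # brighter PCNN class -> dentine; all darker classes -> pulp
        means = {int(c): float(tooth_gray.data[interior & (classes == c)].mean())
                 for c in present}
        dentine_class = max(means, key=means.get)
        roi_labels[interior] = np.where(classes[interior] == dentine_class,
                                        DENTINE, PULP)
    roi_labels[enamel] = ENAMEL
    if not mask.any():
        report_warnings.append("empty segmentation: all-background labels")

    full = np.zeros(vol.shape, dtype=np.int64)
    oz, oy, ox = roi.origin
    nz, ny, nx = roi.shape
    full[oz:oz + nz, oy:oy + ny, ox:ox + nx] = roi_labels

    labels = LabelVolume(full, label_map=dict(DEFAULT_LABEL_MAP),
                         display_gray=dict(DEFAULT_DISPLAY_GRAY),
                         spacing=vol.spacing)
    counts = {name: int(np.count_nonzero(full == lab))
              for lab, name in DEFAULT_LABEL_MAP.items()}
    report = PipelineReport(
        roi_origin=tuple(roi.origin), roi_shape=tuple(roi.shape),
        gfrls_converged=seg.converged, gfrls_iterations=seg.iterations,
        enamel_threshold=eff_threshold,
        tooth_voxels=int(mask.sum()), voxels_per_class=counts,
        warnings=report_warnings)
    return labels, report
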