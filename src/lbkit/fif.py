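"""Fluorescence intensity fluctuation (FIF) spectrometry.

FIF infers the oligomer state of fluorophore-tagged membrane receptors from
photon-counting confocal images of supported plasma membranes.  The membrane
is tiled into small square regions of interest (ROIs, default 15x15 pixels)
and each region's molecular brightness

    epsilon = variance(I) / mean(I) - 1

is computed.  For mobile tagged receptors epsilon is proportional to the
average oligomer size: a pure shot-noise (background) region gives
epsilon = 0, a population of k-mers gives k times the monomer brightness.
Brightness distributions are log-normal, so log10(epsilon) histograms are
fitted with Gaussians (see :mod:`lbkit.gaussfit`) and conditions are
compared with a Z-statistic on the Gaussian means.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .gaussfit import GaussianFit, fit_gaussian_histogram

__all__ = [
    "RoiGrid",
    "BrightnessSample",
    "ZResult",
    "segment_membrane",
    "molecular_brightness",
    "brightness_sample",
    "fit_log_gaussian",
    "z_statistic",
    "estimate_density",
    "load_image",
]

DEFAULT_ROI_SIZE = 15
#: Z threshold above which two brightness populations are called different.
Z_THRESHOLD = 2.0


@dataclasses.dataclass
class RoiGrid:
    """Square pixel blocks tiled over a membrane image, border tiles dropped."""

    image_id: str
    roi_size: int
    rois: np.ndarray  # shape (n_rois, roi_size, roi_size)
    mask_applied: bool

    def __len__(self) -> int:
        return len(self.rois)


@dataclasses.dataclass
class BrightnessSample:
    """Per-ROI molecular brightness values for one experimental condition."""

    condition: str
    epsilon_values: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.epsilon_values = np.asarray(self.epsilon_values, dtype=float)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "roi_index": np.arange(len(self.epsilon_values)),
                "epsilon": self.epsilon_values,
            }
        )


@dataclasses.dataclass
class ZResult:
    z: float
    different: bool

    @property
    def flag(self) -> str:
        return "different" if self.different else "same"


def segment_membrane(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    roi_size: int = DEFAULT_ROI_SIZE,
    image_id: str = "",
) -> RoiGrid:
    """Tile an image into non-overlapping roi_size x roi_size blocks.

    Tiling starts at the top-left origin; partial border tiles are discarded.
    With a mask, only tiles lying entirely inside the mask (all pixels
    nonzero) are kept.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be single-channel 2-D")
    if np.any(image < 0):
        raise ValueError("negative pixel values are not photon counts")
    h, w = image.shape
    if h < roi_size or w < roi_size:
        raise ValueError("image too small")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        mask = mask != 0

    rois = []
    for i in range(0, h - roi_size + 1, roi_size):
        for j in range(0, w - roi_size + 1, roi_size):
            if mask is not None and not mask[i : i + roi_size, j : j + roi_size].all():
                continue
            rois.append(image[i : i + roi_size, j : j + roi_size])
    rois = np.array(rois) if rois else np.empty((0, roi_size, roi_size))
    return RoiGrid(
        image_id=image_id,
        roi_size=roi_size,
        rois=rois,
        mask_applied=mask is not None,
    )


def molecular_brightness(roi: np.ndarray) -> float:
    """Molecular brightness epsilon = variance / mean - 1 of one ROI."""
    roi = np.asarray(roi, dtype=float)
    if roi.size == 0:
        raise ValueError("empty ROI")
    mean = roi.mean()
    if mean <= 0:
        raise ValueError("empty ROI")
    return float(roi.var() / mean - 1.0)


def brightness_sample(
    grids: RoiGrid | list[RoiGrid], condition: str, n_cells: int
) -> BrightnessSample:
    """Collect epsilon over all ROIs of one or more images into a sample.

    ``n_cells`` is supplied as metadata (one image per cell is typical, but
    the caller decides), because the Z-test error ``q`` divides by the number
    of cells analyzed, not the number of ROIs.
    """
    if isinstance(grids, RoiGrid):
        grids = [grids]
    eps = [molecular_brightness(roi) for g in grids for roi in g.rois]
    return BrightnessSample(condition=condition, epsilon_values=np.array(eps), n_cells=n_cells)


def fit_log_gaussian(
    sample: BrightnessSample,
    bin_width: float | None = None,
    min_values: int = 50,
) -> GaussianFit:
    """Fit a Gaussian to the histogram of log10(brightness).

    Brightness distributions are log-normal, so the log-transform is fitted.
    Values epsilon <= 0 have no logarithm and are discarded; the discarded
    fraction is recorded on the returned fit.  Requires at least
    ``min_values`` positive brightness values.
    """
    eps = sample.epsilon_values
    positive = eps[eps > 0]
    discarded = 1.0 - positive.size / eps.size if eps.size else 1.0
    if positive.size < min_values:
        raise ValueError(
            f"need >= {min_values} positive brightness values, got {positive.size}"
        )
    return fit_gaussian_histogram(
        np.log10(positive),
        bin_width=bin_width,
        n_cells=sample.n_cells,
        discarded_fraction=discarded,
    )


def z_statistic(fit1: GaussianFit, fit2: GaussianFit) -> ZResult:
    """Z = |m1 - m2| / sqrt(q1^2 + q2^2) between two Gaussian fits.

    Z > 2 is interpreted as the two populations being different.
    """
    q1, q2 = fit1.q, fit2.q
    if q1 is None or q2 is None:
        raise ValueError("both fits need n_cells to define q")
    denom = np.hypot(q1, q2)
    if denom == 0:
        raise ValueError("degenerate comparison: q1 = q2 = 0")
    z = abs(fit1.m - fit2.m) / denom
    return ZResult(z=float(z), different=bool(z > Z_THRESHOLD))


def estimate_density(
    image: np.ndarray,
    calibration_counts_per_fluorophore: float,
    pixel_area_um2: float,
    mask: np.ndarray | None = None,
    background: float = 0.0,
) -> float:
    """Receptor surface density (per um^2) from mean image intensity.

    density = (mean intensity - background) / (calibration x pixel area).
    ``calibration_counts_per_fluorophore`` comes from imaging fluorescent
    protein standards and is taken as given.
    """
    if calibration_counts_per_fluorophore <= 0:
        raise ValueError("calibration must be positive")
    if pixel_area_um2 <= 0:
        raise ValueError("pixel area must be positive")
    image = np.asarray(image, dtype=float)
    if mask is not None:
        image = image[np.asarray(mask) != 0]
    mean = float(image.mean()) - background
    return max(mean, 0.0) / (calibration_counts_per_fluorophore * pixel_area_um2)


def load_image(path, mask_path=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a single-channel grayscale TIFF and optional nonzero-membrane mask."""
    import tifffile

    image = np.asarray(tifffile.imread(path))
    mask = np.asarray(tifffile.imread(mask_path)) if mask_path else None
    return image, mask


def fits_to_frame(fits: dict[str, GaussianFit]) -> pd.DataFrame:
    """Tabulate per-condition Gaussian fits for CSV export."""
    rows = []
    for condition, f in fits.items():
        rows.append(
            {
                "condition": condition,
                "a": f.a,
                "m": f.m,
                "s": f.s,
                "se_m": f.se_m,
                "se_s": f.se_s,
                "n_cells": f.n_cells,
                "q": f.q,
                "converged": f.converged,
                "discarded_fraction": f.discarded_fraction,
            }
        )
    return pd.DataFrame(rows)
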