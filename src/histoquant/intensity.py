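"""Whole-tissue fluorophore-uptake quantification.

Average per-pixel fluorescence over a tissue ROI that excludes a narrow
border (~10 µm) and any fold/cutting artifacts; control (uninjected or
unstained) tissue is analyzed the same way and reported as a parallel
baseline, never subtracted.  Viable vs. necrotic subregions — delineated
externally from H&E and supplied as masks — are quantified independently and
compared by one-way ANOVA across sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import gaussian, threshold_triangle

__all__ = [
    "ROIMask",
    "RegionAnnotation",
    "IntensityReport",
    "RegionComparison",
    "build_tissue_roi",
    "mean_fluorescence",
    "control_baseline",
    "compare_regions",
    "compare_regions_anova",
    "titration_summary",
]


@dataclass
class ROIMask:
    """Analysis region: tissue foreground minus an edge border and artifacts."""

    mask: np.ndarray
    border_excluded_um: float
    source: str = "auto"  # auto | provided
    empty: bool = False


@dataclass
class RegionAnnotation:
    """Disjoint viable/necrotic region masks (hand-drawn from H&E upstream)."""

    viable_mask: np.ndarray
    necrotic_mask: np.ndarray

    def __post_init__(self) -> None:
        self.viable_mask = np.asarray(self.viable_mask, dtype=bool)
        self.necrotic_mask = np.asarray(self.necrotic_mask, dtype=bool)
        if (self.viable_mask & self.necrotic_mask).any():
            raise ValueError("viable and necrotic masks must be disjoint")


@dataclass
class IntensityReport:
    """Per-section uptake summary: total intensity / pixel over the ROI."""

    condition: str
    mean_intensity: float
    n_pixels: int
    mean_viable: float | None = None
    mean_necrotic: float | None = None
    control_baseline: float | None = None


@dataclass
class RegionComparison:
    mean_overall: float
    n_pixels: int
    mean_viable: float | None
    n_viable: int
    mean_necrotic: float | None
    n_necrotic: int
    mean_other: float | None
    n_other: int


def _erode_by_distance(mask: np.ndarray, n_px: int) -> np.ndarray:
    """Euclidean erosion: keep pixels strictly farther than n_px from background.

    The image boundary counts as background, so a full-frame mask loses
    exactly ``n_px`` rows/columns on each side.
    """
    if n_px <= 0:
        return mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return dist > n_px


def build_tissue_roi(
    channel: np.ndarray,
    pixel_size_um: float,
    border_um: float = 10.0,
    artifact_mask: np.ndarray | None = None,
    tissue_mask: np.ndarray | None = None,
) -> ROIMask:
    """Construct the analysis ROI.

    Tissue foreground is found by triangle thresholding of a Gaussian-smoothed
    (σ = 2 px) channel with hole filling, unless ``tissue_mask`` is provided
    (reproducing a manually drawn ROI).  The foreground is then eroded by
    round(border_um / pixel_size_um) pixels and any artifact pixels removed.
    An empty result is returned flagged, not silently.
    """
    if border_um < 0:
        raise ValueError("border_um must be non-negative")
    channel = np.asarray(channel, dtype=float)
    if tissue_mask is not None:
        fg = np.asarray(tissue_mask, dtype=bool)
        source = "provided"
    else:
        smoothed = gaussian(channel, sigma=2, preserve_range=True)
        if smoothed.max() == smoothed.min():
            fg = np.zeros(channel.shape, dtype=bool)
        else:
            fg = ndi.binary_fill_holes(smoothed > threshold_triangle(smoothed))
        source = "auto"
    n_px = int(round(border_um / pixel_size_um))
    roi = _erode_by_distance(fg, n_px)
    if artifact_mask is not None:
        roi &= ~np.asarray(artifact_mask, dtype=bool)
    empty = not roi.any()
    if empty:
        warnings.warn(
            f"ROI is empty (border {border_um} um exceeds the tissue extent or "
            "no tissue foreground was found)",
            stacklevel=2,
        )
    return ROIMask(mask=roi, border_excluded_um=border_um, source=source, empty=empty)


def mean_fluorescence(channel: np.ndarray, roi: ROIMask) -> tuple[float, int]:
    """Total intensity over the ROI divided by its pixel count."""
    mask = np.asarray(roi.mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot compute mean fluorescence over an empty ROI")
    channel = np.asarray(channel, dtype=float)
    return float(channel[mask].sum() / n), n


def control_baseline(
    control_channels: Sequence[np.ndarray],
    pixel_size_um: float,
    border_um: float = 10.0,
    tissue_masks: Sequence[np.ndarray] | None = None,
) -> float:
    """Autofluorescence baseline: mean of per-control-image ROI means.

    Reported alongside treated-sample means for parallel comparison; it is
    never subtracted from them.
    """
    if not control_channels:
        raise ValueError("control_baseline requires at least one control image")
    means = []
    for i, ch in enumerate(control_channels):
        mask = tissue_masks[i] if tissue_masks is not None else None
        roi = build_tissue_roi(ch, pixel_size_um, border_um, tissue_mask=mask)
        means.append(mean_fluorescence(ch, roi)[0])
    return float(np.mean(means))


def compare_regions(
    channel: np.ndarray, roi: ROIMask, annotation: RegionAnnotation
) -> RegionComparison:
    """Mean intensity over ROI∩viable and ROI∩necrotic (plus the remainder).

    A region with no ROI overlap is reported as absent (None), not zero.  The
    per-pixel sums satisfy the exact conservation identity
    ``n_v·mean_v + n_n·mean_n + n_o·mean_o = n·mean_overall``.
    """
    mask = np.asarray(roi.mask, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    overall, n = mean_fluorescence(channel, roi)

    def region_mean(region: np.ndarray) -> tuple[float | None, int]:
        m = mask & region
        k = int(m.sum())
        return (float(channel[m].mean()) if k else None), k

    mv, nv = region_mean(annotation.viable_mask)
    mn, nn = region_mean(annotation.necrotic_mask)
    mo, no = region_mean(~annotation.viable_mask & ~annotation.necrotic_mask)
    return RegionComparison(overall, n, mv, nv, mn, nn, mo, no)


def compare_regions_anova(
    viable_means: Sequence[float], necrotic_means: Sequence[float]
):
    """One-way ANOVA of per-section viable vs. necrotic mean intensities."""
    from .markers import compare_groups_anova

    return compare_groups_anova({"viable": viable_means, "necrotic": necrotic_means})


def titration_summary(
    reports_by_dose: Mapping[float, Sequence[IntensityReport]],
) -> pd.DataFrame:
    """Dose table: mean intensity ± SEM across replicates per dose.

    Adds a monotone-increasing flag (sign of the Spearman correlation between
    dose and per-dose mean) and flags doses with a single replicate, whose SEM
    is undefined.
    """
    if len(reports_by_dose) < 2:
        raise ValueError("a titration needs at least two doses")
    rows = []
    for dose in sorted(reports_by_dose):
        vals = np.array([r.mean_intensity for r in reports_by_dose[dose]], dtype=float)
        rows.append(
            {
                "dose": dose,
                "n_replicates": len(vals),
                "mean_intensity": vals.mean(),
                "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
                "single_replicate": len(vals) == 1,
            }
        )
    table = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> rho undefined
        rho = stats.spearmanr(table["dose"], table["mean_intensity"]).statistic
    table.attrs["spearman_rho"] = float(rho) if np.isfinite(rho) else np.nan
    table.attrs["monotone_increasing"] = bool(np.isfinite(rho) and rho > 0)
    return table
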