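"""Per-cell marker quantification and viability reporting.

Stained images are normalized against a secondary-only control (which
captures autofluorescence and nonspecific secondary binding), each cell is
scored positive or negative for each marker by supra-threshold overlap with
its nucleus, and section-level calls are pooled into percent-positive
viability reports with SEM across sections.  Group differences are assessed
with one-way ANOVA, the field's default for multi-condition viability
panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .io import TissueImage
from .segmentation import CellPartition, NucleusLabelMap

__all__ = [
    "ControlStats",
    "PositivityRule",
    "ViabilityReport",
    "AnovaResult",
    "normalize_to_control",
    "control_stats",
    "call_positive",
    "summarize_viability",
    "qc_check",
    "compare_groups_anova",
    "per_cell_intensity_table",
]


class ControlStats(NamedTuple):
    """Mean and sd of a secondary-only control channel."""

    mean: float
    sd: float


@dataclass
class PositivityRule:
    """How supra-threshold signal is turned into a per-cell call.

    The binarization threshold is control mean + ``k_sigma``·sd.  For nuclear
    markers a cell is positive when the binarized signal covers at least
    ``min_nuclear_overlap_fraction`` of its nucleus; for cytosolic markers the
    overlap is measured against a 2-px-dilated nucleus rim restricted to the
    cell's own region (the event-counting rule is nuclear overlap for all
    markers, cytosolic ones included).
    """

    compartment: str = "nuclear"  # nuclear | cytosolic
    k_sigma: float = 3.0
    min_nuclear_overlap_fraction: float | None = None  # defaulted per compartment

    NUCLEAR_DEFAULT_OVERLAP = 0.5
    CYTOSOLIC_DEFAULT_OVERLAP = 0.1
    DILATION_PX = 2

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytosolic"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_nuclear_overlap_fraction is None:
            self.min_nuclear_overlap_fraction = (
                self.NUCLEAR_DEFAULT_OVERLAP
                if self.compartment == "nuclear"
                else self.CYTOSOLIC_DEFAULT_OVERLAP
            )
        if not 0 < self.min_nuclear_overlap_fraction <= 1:
            raise ValueError("min_nuclear_overlap_fraction must lie in (0, 1]")


def control_stats(control_channel: np.ndarray) -> ControlStats:
    ch = np.asarray(control_channel, dtype=float)
    return ControlStats(float(ch.mean()), float(ch.std()))


def normalize_to_control(stained: TissueImage, control: TissueImage) -> TissueImage:
    """Subtract the control channel mean from each stained channel, clipped at 0.

    The secondary-only control captures additive autofluorescence, so its
    per-channel mean is removed; the subtracted means are recorded in the
    output metadata.
    """
    missing = set(stained.channels) - set(control.channels)
    if missing:
        raise ValueError(
            f"control image lacks channel(s) {sorted(missing)} present in the stained image"
        )
    out_channels = {}
    out_meta = {}
    for name, ch in stained.channels.items():
        mu = float(control.channels[name].mean())
        out_channels[name] = np.clip(ch - mu, 0, None)
        meta = dict(stained.channel_meta.get(name, {}))
        meta["control_mean_subtracted"] = mu
        out_meta[name] = meta
    return TissueImage(out_channels, stained.pixel_size_um, out_meta)


def call_positive(
    cells: CellPartition,
    nuclei: NucleusLabelMap,
    marker_channel: np.ndarray,
    control: ControlStats,
    rule: PositivityRule,
    marker_name: str = "marker",
) -> pd.DataFrame:
    """Score every segmented cell for one marker.

    Returns one row per nucleus label with mean nuclear / whole-cell
    intensities and the boolean call.
    """
    marker_channel = np.asarray(marker_channel, dtype=float)
    if marker_channel.shape != nuclei.labels.shape:
        raise ValueError("marker channel dimensions differ from the label maps")
    if control.sd < 0:
        raise ValueError("control sd must be non-negative")
    n = nuclei.n_nuclei
    idx = np.arange(1, n + 1)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "nucleus_label",
                "marker_name",
                "mean_intensity_nuclear",
                "mean_intensity_cell",
                "positive",
            ]
        )

    threshold = control.mean + rule.k_sigma * control.sd
    supra = marker_channel > threshold

    mean_nuc = ndi.mean(marker_channel, labels=nuclei.labels, index=idx)
    mean_cell = ndi.mean(marker_channel, labels=cells.cell_labels, index=idx)

    if rule.compartment == "nuclear":
        region = nuclei.labels
    else:
        # 2-px-dilated nucleus rim, clipped to the cell's own region
        rim = cells.distance_map <= rule.DILATION_PX * cells.pixel_size_um
        region = np.where(rim, cells.cell_labels, 0)
    region_area = ndi.sum_labels(np.ones_like(region, dtype=float), labels=region, index=idx)
    overlap = ndi.sum_labels(supra.astype(float), labels=region, index=idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(region_area > 0, overlap / region_area, 0.0)
    positive = frac >= rule.min_nuclear_overlap_fraction

    return pd.DataFrame(
        {
            "nucleus_label": idx,
            "marker_name": marker_name,
            "mean_intensity_nuclear": mean_nuc,
            "mean_intensity_cell": mean_cell,
            "positive": positive,
        }
    )


@dataclass
class ViabilityReport:
    """Percent-positive statistics per (condition, marker)."""

    table: pd.DataFrame  # condition, marker, n_cells, n_positive, percent_positive, sem, n_sections, n_rois

    def row(self, condition: str, marker: str) -> pd.Series:
        t = self.table
        sel = t[(t["condition"] == condition) & (t["marker"] == marker)]
        if sel.empty:
            raise KeyError(f"no entry for condition={condition!r}, marker={marker!r}")
        return sel.iloc[0]


def summarize_viability(
    tables_by_condition: Mapping[str, Sequence[pd.DataFrame]],
    rois_per_section: int = 1,
) -> ViabilityReport:
    """Pool per-section marker-call tables into a viability report.

    ``percent_positive`` is 100·Σ positives / Σ cells pooled over sections;
    SEM is computed across section-level percentages (the section is the
    biological replicate).  ``rois_per_section`` only scales the reported ROI
    count for QC purposes.
    """
    if not tables_by_condition:
        raise ValueError("summarize_viability requires at least one condition")
    rows = []
    for condition, tables in tables_by_condition.items():
        if not tables:
            raise ValueError(f"condition {condition!r} has no sections")
        markers = sorted({m for t in tables for m in t["marker_name"].unique()})
        for marker in markers:
            per_section = []
            n_cells = n_pos = 0
            for t in tables:
                sub = t[t["marker_name"] == marker]
                nc, np_ = len(sub), int(sub["positive"].sum())
                n_cells += nc
                n_pos += np_
                if nc:
                    per_section.append(100.0 * np_ / nc)
            pct = 100.0 * n_pos / n_cells if n_cells else np.nan
            sem = stats.sem(per_section) if len(per_section) > 1 else 0.0
            rows.append(
                {
                    "condition": condition,
                    "marker": marker,
                    "n_cells": n_cells,
                    "n_positive": n_pos,
                    "percent_positive": pct,
                    "sem": float(sem),
                    "n_sections": len(tables),
                    "n_rois": len(tables) * rois_per_section,
                }
            )
    return ViabilityReport(pd.DataFrame(rows))


def qc_check(
    report: ViabilityReport, min_total_nuclei: int = 5000, min_rois: int = 10
) -> pd.DataFrame:
    """Flag conditions that miss the analysis floor (≥5000 nuclei, ≥10 ROIs).

    Failing conditions are reported with reasons, never dropped.
    """
    rows = []
    for (condition,), grp in report.table.groupby(["condition"]):
        n_nuclei = int(grp["n_cells"].iloc[0])
        n_rois = int(grp["n_rois"].iloc[0])
        reasons = []
        if n_nuclei < min_total_nuclei:
            reasons.append("min_total_nuclei")
        if n_rois < min_rois:
            reasons.append("min_rois")
        rows.append(
            {
                "condition": condition,
                "n_nuclei": n_nuclei,
                "n_rois": n_rois,
                "passed": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    statistic: float
    pvalue: float
    group_means: pd.DataFrame  # group, n, mean, sem


def compare_groups_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across named groups of section-level values."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than two values")
        arrays[name] = arr
    res = stats.f_oneway(*arrays.values())
    f = float(res.statistic)
    if not np.isfinite(f):  # identical constant groups: zero between-group variance
        f, p = 0.0, 1.0
    else:
        p = float(res.pvalue)
    means = pd.DataFrame(
        {
            "group": list(arrays),
            "n": [len(a) for a in arrays.values()],
            "mean": [a.mean() for a in arrays.values()],
            "sem": [stats.sem(a) for a in arrays.values()],
        }
    )
    return AnovaResult(f, p, means)


def per_cell_intensity_table(
    cells: CellPartition, nuclei: NucleusLabelMap, channel: np.ndarray
) -> pd.DataFrame:
    """Mean channel intensity per cell region and per nucleus, one row per cell.

    The raw material for dose-titration and competitive-binding style
    single-cell summaries.
    """
    channel = np.asarray(channel, dtype=float)
    n = nuclei.n_nuclei
    idx = np.arange(1, n + 1)
    if n == 0:
        return pd.DataFrame(columns=["nucleus_label", "mean_intensity_nuclear", "mean_intensity_cell"])
    return pd.DataFrame(
        {
            "nucleus_label": idx,
            "mean_intensity_nuclear": ndi.mean(channel, labels=nuclei.labels, index=idx),
            "mean_intensity_cell": ndi.mean(channel, labels=cells.cell_labels, index=idx),
        }
    )
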