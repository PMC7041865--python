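"""End-to-end convenience wrappers: scene/image → per-cell calls → reports.

These glue the segmentation and marker-quantification stages together the
way a viability study runs them: segment the DAPI channel, normalize every
marker channel to the secondary-only control, and call positivity per cell.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import TissueImage
from .markers import (
    ControlStats,
    PositivityRule,
    call_positive,
    normalize_to_control,
)
from .segmentation import SegmentationConfig, segment

__all__ = ["quantify_section", "default_rules_for"]


def default_rules_for(img: TissueImage) -> dict[str, PositivityRule]:
    """Positivity rules per marker channel, using the recorded compartment.

    Channels without compartment metadata default to nuclear scoring.
    """
    rules = {}
    for name in img.channel_names():
        if name == "DAPI":
            continue
        compartment = img.channel_meta.get(name, {}).get("compartment", "nuclear")
        if compartment == "whole_tissue":
            continue
        rules[name] = PositivityRule(compartment=compartment)
    return rules


def quantify_section(
    stained: TissueImage,
    control: TissueImage,
    config: SegmentationConfig | None = None,
    rules: Mapping[str, PositivityRule] | None = None,
    artifact_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Segment one section and call positivity for every marker channel.

    Marker channels are normalized to the secondary-only control; the
    binarization threshold for each marker comes from the statistics of the
    control channel normalized the same way.  Returns the concatenated
    per-cell :func:`call_positive` tables (one row per cell and marker).
    """
    normalized = normalize_to_control(stained, control)
    nuclei, cells = segment(normalized, config, artifact_mask=artifact_mask)
    if rules is None:
        rules = default_rules_for(stained)
    frames = []
    for name, rule in rules.items():
        ctrl_norm = np.clip(
            control.channel(name) - float(control.channel(name).mean()), 0, None
        )
        stats = ControlStats(float(ctrl_norm.mean()), float(ctrl_norm.std()))
        frames.append(
            call_positive(
                cells, nuclei, normalized.channel(name), stats, rule, marker_name=name
            )
        )
    if not frames:
        raise ValueError("no marker channels to quantify")
    return pd.concat(frames, ignore_index=True)
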